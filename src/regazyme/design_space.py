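"""Designability analysis of the transducer sequence space.

Random sampling of candidate scores, Sarle's bimodality coefficient for
the per-axis score distributions, anchored IUPAC consensus of optimized
solutions, a pairwise mediator/target interaction-energy matrix for
cross-talk screening, and combinatorial circuit counting.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .folding import FoldingEngine, get_engine, validate_rna
from .objective import score_design
from .parts import RegazymeLayout, assemble, random_transducer

__all__ = [
    "sample_scores",
    "bimodality_coefficient",
    "BC_UNIFORM_THRESHOLD",
    "ConsensusResult",
    "consensus",
    "crosstalk_matrix",
    "orthogonality_report",
    "circuit_count",
]

#: Sarle's BC of the uniform distribution — the conventional unimodality
#: benchmark: values above 5/9 suggest bimodality.
BC_UNIFORM_THRESHOLD = 5.0 / 9.0

IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("U"): "U",
    frozenset("AG"): "R",
    frozenset("CU"): "Y",
    frozenset("GU"): "K",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
    frozenset("AU"): "W",
    frozenset("CGU"): "B",
    frozenset("AGU"): "D",
    frozenset("ACU"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGU"): "N",
}

IUPAC_CLASSES = {code: set(bases) for bases, code in IUPAC_CODES.items()}


def sample_scores(
    layout: RegazymeLayout,
    n: int,
    engine: FoldingEngine | str = "toy",
    rng: np.random.Generator | int | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Score ``n`` independent random transducers (one row each)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(rng)
    eng = get_engine(engine)
    rows = []
    for _ in range(n):
        tr = {
            p.name: random_transducer(layout.transducer_length_bounds, rng)
            for p in layout.mutable_parts
        }
        design = assemble(layout, tr)
        s = score_design(design, eng, weights)
        rows.append(
            {
                "transducer": design.transducer_sequence,
                "d_apt": s.d_apt,
                "d_seed_pre": s.d_seed_pre,
                "d_seed_post": s.d_seed_post,
                "total": s.total,
                "mfe_uncleaved": s.mfe_uncleaved,
                "mfe_fragment": s.mfe_fragment,
            }
        )
    columns = [
        "transducer", "d_apt", "d_seed_pre", "d_seed_post",
        "total", "mfe_uncleaved", "mfe_fragment",
    ]
    return pd.DataFrame(rows, columns=columns)


def bimodality_coefficient(values) -> float:
    """Sarle's sample-size-corrected bimodality coefficient.

    BC = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))) with g1 the sample
    skewness and g2 the sample excess kurtosis.  Uniform data give 5/9 in
    the large-n limit, normal data 1/3, and a balanced two-point mixture
    approaches 1.  Requires n >= 4 and non-constant values.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("bimodality coefficient needs at least 4 values")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("bimodality coefficient undefined for constant values")
    g1 = stats.skew(x, bias=True)
    g2 = stats.kurtosis(x, fisher=True, bias=True)
    correction = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g1**2 + 1.0) / (g2 + correction))


@dataclass
class ConsensusResult:
    """Anchor-aligned consensus of designed sequences."""

    consensus: str
    anchor_span: tuple[int, int]  # columns occupied by the anchor motif
    conservation: list[float]  # per-column fraction of the modal base
    columns: list[dict[str, int]]  # per-column base counts
    used: list[str]
    excluded: list[str]


def _motif_regex(motif: str) -> re.Pattern[str]:
    parts = []
    for ch in motif.upper().replace("T", "U"):
        if ch not in IUPAC_CLASSES:
            raise ValueError(f"invalid IUPAC code {ch!r} in anchor motif")
        bases = sorted(IUPAC_CLASSES[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def consensus(sequences: list[str], anchor_motif: str) -> ConsensusResult:
    """Ungapped anchor-registered alignment with per-column IUPAC consensus.

    Each sequence is shifted so that its first occurrence of
    ``anchor_motif`` falls on the same columns; the consensus letter of a
    column is the IUPAC code covering exactly the set of bases observed
    there.  Sequences lacking the anchor are excluded with a warning.
    """
    pattern = _motif_regex(anchor_motif)
    used, offsets, excluded = [], [], []
    for seq in sequences:
        s = validate_rna(seq)
        m = pattern.search(s)
        if m is None:
            excluded.append(s)
            warnings.warn(
                f"sequence {s!r} lacks anchor {anchor_motif!r}; excluded",
                stacklevel=2,
            )
        else:
            used.append(s)
            offsets.append(m.start())
    if not used:
        raise ValueError("no sequence contains the anchor motif")

    left = max(offsets)
    width = max(left + len(s) - off for s, off in zip(used, offsets))
    letters, conservation, columns = [], [], []
    for col in range(width):
        counts: dict[str, int] = {}
        for s, off in zip(used, offsets):
            k = col - (left - off)
            if 0 <= k < len(s):
                counts[s[k]] = counts.get(s[k], 0) + 1
        columns.append(counts)
        if not counts:
            letters.append("-")
            conservation.append(0.0)
        else:
            letters.append(IUPAC_CODES[frozenset(counts)])
            conservation.append(max(counts.values()) / sum(counts.values()))
    return ConsensusResult(
        consensus="".join(letters),
        anchor_span=(left, left + len(anchor_motif)),
        conservation=conservation,
        columns=columns,
        used=used,
        excluded=excluded,
    )


def crosstalk_matrix(
    mediators: list[str],
    targets: list[str],
    engine: FoldingEngine | str = "toy",
    mediator_names: list[str] | None = None,
    target_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise mediator→target interaction energies (kcal/mol, ≤ 0)."""
    eng = get_engine(engine)
    mediator_names = mediator_names or [f"mediator_{k}" for k in range(len(mediators))]
    target_names = target_names or [f"target_{k}" for k in range(len(targets))]
    data = [
        [eng.duplex(m, t).energy for t in targets] for m in mediators
    ]
    return pd.DataFrame(
        np.array(data, dtype=float).reshape(len(mediators), len(targets)),
        index=mediator_names,
        columns=target_names,
    )


def orthogonality_report(matrix: pd.DataFrame, margin: float = 2.0) -> pd.DataFrame:
    """Flag off-diagonal interactions within ``margin`` kcal/mol of the cognate.

    Expects a square matrix whose diagonal holds the cognate pairs.  Rows
    of the result name (mediator, target, energy, cognate energy).
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("orthogonality report expects a square cognate matrix")
    flags = []
    for i, med in enumerate(matrix.index):
        cognate = matrix.iat[i, i]
        for j, tgt in enumerate(matrix.columns):
            if i != j and matrix.iat[i, j] <= cognate + margin:
                flags.append(
                    {
                        "mediator": med,
                        "target": tgt,
                        "energy": matrix.iat[i, j],
                        "cognate_energy": cognate,
                    }
                )
    return pd.DataFrame(flags, columns=["mediator", "target", "energy", "cognate_energy"])


def circuit_count(N: int, M: int, P: int) -> int:
    """Number of distinct circuits of P regazymes from N sensors × M mediators."""
    if min(N, M, P) < 0:
        raise ValueError("N, M, P must be non-negative")
    return (N * M) ** P
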