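"""RNA secondary-structure engines.

Two interchangeable engines sit behind one contract: minimum-free-energy
folding of a single strand (:meth:`FoldingEngine.mfe_fold`) and the
interaction energy of two strands (:meth:`FoldingEngine.duplex`).

* :class:`NussinovEngine` — a deterministic maximum-base-pairing model
  (Watson–Crick plus G·U wobble, hairpin loops of at least three unpaired
  nucleotides, energy −1 kcal/mol per pair).  Every structure it returns is
  exactly reproducible and independent of any thermodynamic parameter set,
  which makes design-space and annealing tests exact.
* :class:`ViennaEngine` — nearest-neighbour thermodynamics via the
  ViennaRNA bindings (``import RNA``), for realistic design work.

Structures are dot-bracket strings without pseudoknots.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "FoldResult",
    "DuplexResult",
    "FoldingEngine",
    "NussinovEngine",
    "ViennaEngine",
    "get_engine",
    "validate_rna",
    "validate_structure",
    "pair_table",
    "CAN_PAIR",
]

RNA_ALPHABET = frozenset("ACGU")

#: canonical pairs: Watson-Crick and G-U wobble
CAN_PAIR = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: minimum number of unpaired nucleotides enclosed by a hairpin-closing pair
MIN_HAIRPIN = 3


def validate_rna(sequence: str, *, allow_empty: bool = False) -> str:
    """Return ``sequence`` uppercased with T transcribed to U, or raise ValueError."""
    if not isinstance(sequence, str):
        raise ValueError(f"RNA sequence must be a string, got {type(sequence).__name__}")
    seq = sequence.upper().replace("T", "U")
    if not seq and not allow_empty:
        raise ValueError("RNA sequence must be non-empty")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA characters {sorted(bad)} in {sequence!r}")
    return seq


def validate_structure(structure: str, sequence: str | None = None) -> None:
    """Check a dot-bracket string: balanced, non-crossing, canonical pairs.

    Crossing (pseudoknotted) input cannot be expressed with a single bracket
    type, so balance checking already excludes it.  When ``sequence`` is
    given, also require canonical pairing and the minimum hairpin size.
    """
    if re.fullmatch(r"[().]*", structure) is None:
        raise ValueError(f"invalid dot-bracket characters in {structure!r}")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i} in {structure!r}")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]} in {structure!r}")
    if sequence is not None:
        if len(sequence) != len(structure):
            raise ValueError("sequence and structure lengths differ")
        for i, j in pairs:
            if (sequence[i], sequence[j]) not in CAN_PAIR:
                raise ValueError(
                    f"non-canonical pair {sequence[i]}{sequence[j]} at ({i},{j})"
                )
            if j - i - 1 < MIN_HAIRPIN and ")" not in structure[i + 1 : j]:
                raise ValueError(f"hairpin loop at ({i},{j}) shorter than {MIN_HAIRPIN}")


def pair_table(structure: str) -> list[int]:
    """Map each position to its partner index, or -1 when unpaired."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            table[i], table[j] = j, i
    return table


@dataclass(frozen=True)
class FoldResult:
    """A folded strand: sequence, dot-bracket structure, free energy (kcal/mol)."""

    sequence: str
    structure: str
    energy: float

    def __post_init__(self) -> None:
        validate_structure(self.structure, self.sequence)

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


@dataclass(frozen=True)
class DuplexResult:
    """Intermolecular interaction between two strands.

    ``pairs`` maps positions of strand A onto positions of strand B
    (0-based, within each strand).  ``energy`` is 0 with an empty pairing
    when no favourable interaction exists, negative otherwise.
    """

    seq_a: str
    seq_b: str
    pairs: tuple[tuple[int, int], ...]
    energy: float

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if not (0 <= i < len(self.seq_a) and 0 <= j < len(self.seq_b)):
                raise ValueError(f"duplex pair ({i},{j}) outside strand bounds")


class FoldingEngine:
    """Contract every structure engine satisfies."""

    name = "abstract"

    def mfe_fold(self, sequence: str) -> FoldResult:  # pragma: no cover - interface
        raise NotImplementedError

    def duplex(self, seq_a: str, seq_b: str) -> DuplexResult:  # pragma: no cover
        raise NotImplementedError


class NussinovEngine(FoldingEngine):
    """Deterministic maximum-pairing engine.

    Folding maximises the number of canonical pairs subject to a minimum
    hairpin of three unpaired nucleotides.  Among maximum-pairing structures
    the tie is broken deterministically: scanning 5'→3', a position is
    paired whenever pairing it still attains the maximum, and its 5'-most
    feasible partner is chosen.  Energy is −1 kcal/mol per pair.

    Duplex interaction is the maximum non-crossing set of intermolecular
    canonical pairs between the two antiparallel strands, again at
    −1 kcal/mol per pair.
    """

    name = "toy"

    def __init__(self, cache_size: int = 100_000) -> None:
        self._fold_cached = lru_cache(maxsize=cache_size)(self._fold_impl)

    def mfe_fold(self, sequence: str) -> FoldResult:
        seq = validate_rna(sequence)
        structure = self._fold_cached(seq)
        return FoldResult(seq, structure, -1.0 * structure.count("("))

    @staticmethod
    def _fold_impl(seq: str) -> str:
        n = len(seq)
        # N[i][j] = max pairs in seq[i..j] inclusive
        N = [[0] * n for _ in range(n)]
        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(n - span):
                j = i + span
                best = N[i + 1][j]
                for k in range(i + MIN_HAIRPIN + 1, j + 1):
                    if (seq[i], seq[k]) in CAN_PAIR:
                        inner = N[i + 1][k - 1] if k - 1 >= i + 1 else 0
                        outer = N[k + 1][j] if k + 1 <= j else 0
                        best = max(best, 1 + inner + outer)
                N[i][j] = best
        structure = ["."] * n

        def trace(i: int, j: int) -> None:
            while i < j:
                target = N[i][j]
                if target == 0:
                    return
                paired = False
                for k in range(i + MIN_HAIRPIN + 1, j + 1):
                    if (seq[i], seq[k]) in CAN_PAIR:
                        inner = N[i + 1][k - 1] if k - 1 >= i + 1 else 0
                        outer = N[k + 1][j] if k + 1 <= j else 0
                        if 1 + inner + outer == target:
                            structure[i], structure[k] = "(", ")"
                            trace(i + 1, k - 1)
                            i = k + 1
                            paired = True
                            break
                if not paired:
                    i += 1  # position i stays unpaired

        if n > 0:
            trace(0, n - 1)
        return "".join(structure)

    def duplex(self, seq_a: str, seq_b: str) -> DuplexResult:
        a = validate_rna(seq_a)
        b = validate_rna(seq_b)
        # Antiparallel non-crossing intermolecular pairing: position i of A
        # ascending pairs position j of B descending.  This is an LCS-style
        # DP of A against reversed B under complementarity.
        br = b[::-1]
        na, nb = len(a), len(br)
        D = [[0] * (nb + 1) for _ in range(na + 1)]
        for i in range(na - 1, -1, -1):
            for j in range(nb - 1, -1, -1):
                best = max(D[i + 1][j], D[i][j + 1])
                if (a[i], br[j]) in CAN_PAIR:
                    best = max(best, 1 + D[i + 1][j + 1])
                D[i][j] = best
        pairs: list[tuple[int, int]] = []
        i = j = 0
        while i < na and j < nb:
            if (a[i], br[j]) in CAN_PAIR and D[i][j] == 1 + D[i + 1][j + 1]:
                pairs.append((i, nb - 1 - j))
                i, j = i + 1, j + 1
            elif D[i + 1][j] >= D[i][j + 1]:
                i += 1
            else:
                j += 1
        return DuplexResult(a, b, tuple(pairs), -1.0 * len(pairs))


class ViennaEngine(FoldingEngine):
    """Nearest-neighbour thermodynamic engine (ViennaRNA bindings)."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - present in target env
            raise ImportError(
                "the 'vienna' engine needs the ViennaRNA Python bindings "
                "(conda package 'viennarna'); use engine='toy' otherwise"
            ) from exc
        self._rna = RNA
        self.version = getattr(RNA, "__version__", "unknown")
        self._fold_cached = lru_cache(maxsize=100_000)(self._fold_impl)

    def mfe_fold(self, sequence: str) -> FoldResult:
        seq = validate_rna(sequence)
        structure, energy = self._fold_cached(seq)
        return FoldResult(seq, structure, energy)

    def _fold_impl(self, seq: str) -> tuple[str, float]:
        structure, energy = self._rna.fold(seq)
        return structure, float(energy)

    def duplex(self, seq_a: str, seq_b: str) -> DuplexResult:
        a = validate_rna(seq_a)
        b = validate_rna(seq_b)
        dup = self._rna.duplexfold(a, b)
        if dup.energy >= 0:
            return DuplexResult(a, b, (), 0.0)
        # duplexfold structure: "...((..&..))..." with i/j the 3' ends of the
        # paired regions on each strand (1-based).
        part_a, part_b = dup.structure.split("&")
        open_pos = [k for k, c in enumerate(part_a) if c == "("]
        close_pos = [k for k, c in enumerate(part_b) if c == ")"]
        a_start = dup.i - len(part_a)  # 0-based start of part_a on strand A
        b_start = dup.j - 1  # 0-based start of part_b on strand B
        pairs = tuple(
            (a_start + pa, b_start + pb)
            for pa, pb in zip(open_pos, reversed(close_pos))
        )
        return DuplexResult(a, b, pairs, float(dup.energy))


_ENGINES = {"toy": NussinovEngine, "vienna": ViennaEngine}


def get_engine(name: str | FoldingEngine) -> FoldingEngine:
    """Resolve an engine by name ('toy' or 'vienna') or pass one through."""
    if isinstance(name, FoldingEngine):
        return name
    try:
        return _ENGINES[name]()
    except KeyError:
        raise ValueError(f"unknown engine {name!r}; choose from {sorted(_ENGINES)}")
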