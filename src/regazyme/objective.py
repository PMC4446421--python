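"""Three-term structural penalty for candidate regazymes.

A candidate is folded in both conformational states and penalised for
(i) the aptamer region deviating from its functional target structure in
the uncleaved state (proxy for the activation energy of catalysis),
(ii) riboregulator seed positions left *unpaired* before cleavage
(premature mediator exposure), and (iii) seed positions left *paired* in
the released 3' fragment (mediator obstruction after cleavage).  Each term
is a Hamming-style count; an ideal design scores zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .folding import FoldingEngine, get_engine
from .parts import RegazymeDesign, cleave

__all__ = ["ScoreComponents", "structure_hamming", "score_design", "total_score"]


@dataclass(frozen=True)
class ScoreComponents:
    """The three penalty terms, their weighted total, and logged energies."""

    d_apt: int
    d_seed_pre: int
    d_seed_post: int
    total: float
    mfe_uncleaved: float = 0.0
    mfe_fragment: float = 0.0

    def __post_init__(self) -> None:
        if min(self.d_apt, self.d_seed_pre, self.d_seed_post) < 0:
            raise ValueError("penalty components must be non-negative")


def structure_hamming(a: str, b: str) -> int:
    """Positions at which two equal-length dot-bracket strings differ."""
    if len(a) != len(b):
        raise ValueError(f"structure lengths differ ({len(a)} vs {len(b)})")
    return sum(ca != cb for ca, cb in zip(a, b))


def _paired_mismatch(a: str, b: str) -> int:
    """Hamming distance on the paired/unpaired projection of two structures."""
    if len(a) != len(b):
        raise ValueError(f"structure lengths differ ({len(a)} vs {len(b)})")
    return sum((ca == ".") != (cb == ".") for ca, cb in zip(a, b))


def total_score(
    components: tuple[int, int, int], weights: tuple[float, float, float]
) -> float:
    """Weighted sum of the three penalty terms (weights strictly positive)."""
    if min(weights) <= 0:
        raise ValueError("objective weights must be strictly positive")
    return float(sum(w * c for w, c in zip(weights, components)))


def score_design(
    design: RegazymeDesign,
    engine: FoldingEngine | str = "toy",
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    *,
    paired_only: bool = False,
) -> ScoreComponents:
    """Fold both states of a design and return its penalty components.

    One fold of the uncleaved assembled sequence and one of the cleaved
    3' fragment.  ``paired_only=True`` compares the aptamer region to its
    target on the paired/unpaired projection instead of the full
    {'(', ')', '.'} alphabet.
    """
    eng = get_engine(engine)
    uncleaved = eng.mfe_fold(design.assembled)
    _, frag3 = cleave(design)
    fragment = eng.mfe_fold(frag3)

    a0, a1 = design.aptamer_interval
    apt_struct = uncleaved.structure[a0:a1]
    target = design.layout.target_aptamer_structure
    dist = _paired_mismatch if paired_only else structure_hamming
    d_apt = dist(apt_struct, target)

    s0, s1 = design.seed_interval
    d_seed_pre = uncleaved.structure[s0:s1].count(".")
    bond = design.cleavage_bond
    frag_seed = fragment.structure[s0 - bond : s1 - bond]
    d_seed_post = sum(c != "." for c in frag_seed)

    return ScoreComponents(
        d_apt,
        d_seed_pre,
        d_seed_post,
        total_score((d_apt, d_seed_pre, d_seed_post), weights),
        mfe_uncleaved=uncleaved.energy,
        mfe_fragment=fragment.energy,
    )
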