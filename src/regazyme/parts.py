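"""Regazyme architecture: ordered sequence parts, assembly, cleavage, moves.

A regazyme fuses an aptazyme (sensor) to a riboregulator (mediator) through
a designed transducer stem.  The layout declares the fixed parts in 5'→3'
order, which part is the designable transducer, where the self-cleavage
bond sits (a phosphodiester bond between two named parts), where the
riboregulator seed lies, and the target secondary structure of the aptamer
region.  All coordinates are 0-based with half-open intervals; the cleavage
site is a bond index ``b`` cutting between assembled positions ``b-1`` and
``b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .folding import validate_rna, validate_structure

__all__ = [
    "ROLES",
    "Part",
    "RegionRef",
    "RegazymeLayout",
    "RegazymeDesign",
    "assemble",
    "cleave",
    "random_transducer",
    "mutate",
    "MoveError",
]

ROLES = (
    "fixed_5p",
    "aptamer",
    "ribozyme_core",
    "transducer",
    "riboregulator",
    "terminator",
)

MOVES = ("substitution", "insertion", "deletion")

BASES = ("A", "C", "G", "U")


class MoveError(RuntimeError):
    """No feasible mutation move exists under the given weights and bounds."""


@dataclass(frozen=True)
class Part:
    """One named segment of the regazyme.

    Fixed parts carry their sequence; the mutable transducer's sequence is
    supplied per design (its ``sequence`` here is an optional starting
    point and may be empty).
    """

    name: str
    role: str
    sequence: str = ""
    mutable: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown part role {self.role!r}; choose from {ROLES}")
        if self.mutable and self.role != "transducer":
            raise ValueError(f"only transducer parts may be mutable ({self.name})")
        seq = validate_rna(self.sequence, allow_empty=True)
        if not self.mutable and not seq:
            raise ValueError(f"fixed part {self.name!r} must have a sequence")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class RegionRef:
    """A half-open interval relative to a named part."""

    part: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start},{self.end}) in {self.part}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegazymeLayout:
    """Ordered parts plus the design annotations.

    ``cleavage_after`` names the part whose 3' end is the cleavage site
    (the bond between that part and the next).  ``seed`` and ``aptamer``
    are part-relative regions; their absolute coordinates are computed per
    assembled design since the transducer length varies.
    """

    parts: tuple[Part, ...]
    cleavage_after: str
    seed: RegionRef
    target_aptamer_structure: str
    aptamer: RegionRef | None = None
    transducer_length_bounds: tuple[int, int] = (0, 30)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parts", tuple(self.parts))
        names = [p.name for p in self.parts]
        if len(set(names)) != len(names):
            raise ValueError("part names must be unique")
        mutable = [p for p in self.parts if p.mutable]
        if not mutable:
            raise ValueError("layout needs at least one mutable transducer part")
        lo, hi = self.transducer_length_bounds
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid transducer length bounds ({lo},{hi})")
        if self.cleavage_after not in names[:-1]:
            raise ValueError(
                f"cleavage_after={self.cleavage_after!r} must name a non-terminal part"
            )
        # resolve the aptamer region: explicit ref or the 'aptamer' role part
        apt = self.aptamer
        if apt is None:
            apt_parts = [p for p in self.parts if p.role == "aptamer"]
            if len(apt_parts) != 1:
                raise ValueError(
                    "layout needs an explicit aptamer region or exactly one "
                    "part with role 'aptamer'"
                )
            apt = RegionRef(apt_parts[0].name, 0, len(apt_parts[0].sequence))
            object.__setattr__(self, "aptamer", apt)
        for ref in (self.seed, self.aptamer):
            part = self.part(ref.part)
            if not part.mutable and ref.end > len(part.sequence):
                raise ValueError(f"region {ref} exceeds part {part.name!r}")
        if len(self.target_aptamer_structure) != self.aptamer.length:
            raise ValueError("target aptamer structure length != aptamer region length")
        validate_structure(self.target_aptamer_structure)
        # the seed must ride on the released 3' fragment
        order = {n: k for k, n in enumerate(names)}
        if order[self.seed.part] <= order[self.cleavage_after]:
            raise ValueError("seed region must lie downstream of the cleavage bond")

    def part(self, name: str) -> Part:
        for p in self.parts:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def mutable_parts(self) -> tuple[Part, ...]:
        return tuple(p for p in self.parts if p.mutable)

    @property
    def seed_length(self) -> int:
        return self.seed.length


@dataclass(frozen=True)
class RegazymeDesign:
    """A concrete regazyme: layout + transducer sequence(s), fully assembled."""

    layout: RegazymeLayout
    transducers: dict[str, str]
    assembled: str = field(init=False, default="")
    index_map: dict[str, tuple[int, int]] = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.layout.transducer_length_bounds
        tr = {}
        for part in self.layout.mutable_parts:
            if part.name not in self.transducers:
                raise ValueError(f"missing transducer sequence for {part.name!r}")
            seq = validate_rna(self.transducers[part.name], allow_empty=True)
            if not (lo <= len(seq) <= hi):
                raise ValueError(
                    f"transducer {part.name!r} length {len(seq)} outside bounds "
                    f"[{lo},{hi}]"
                )
            tr[part.name] = seq
        extra = set(self.transducers) - set(tr)
        if extra:
            raise ValueError(f"unknown transducer names {sorted(extra)}")
        object.__setattr__(self, "transducers", tr)
        pieces, index_map, pos = [], {}, 0
        for part in self.layout.parts:
            seq = tr[part.name] if part.mutable else part.sequence
            index_map[part.name] = (pos, pos + len(seq))
            pieces.append(seq)
            pos += len(seq)
        object.__setattr__(self, "assembled", "".join(pieces))
        object.__setattr__(self, "index_map", index_map)

    @property
    def transducer_sequence(self) -> str:
        """The single designable sequence (joined when two arms are designed)."""
        return "".join(self.transducers[p.name] for p in self.layout.mutable_parts)

    @property
    def cleavage_bond(self) -> int:
        """Absolute bond index: cut between positions bond-1 and bond."""
        return self.index_map[self.layout.cleavage_after][1]

    def _absolute(self, ref: RegionRef) -> tuple[int, int]:
        start, end = self.index_map[ref.part]
        if ref.end > end - start:
            raise ValueError(f"region {ref} exceeds part extent in this design")
        return (start + ref.start, start + ref.end)

    @property
    def seed_interval(self) -> tuple[int, int]:
        return self._absolute(self.layout.seed)

    @property
    def aptamer_interval(self) -> tuple[int, int]:
        return self._absolute(self.layout.aptamer)


def assemble(layout: RegazymeLayout, transducer: str | dict[str, str]) -> RegazymeDesign:
    """Build a design by substituting the transducer sequence(s) into the layout.

    ``transducer`` is a plain string when the layout has a single mutable
    part, or a mapping part name → sequence when both arms are designed.
    """
    if isinstance(transducer, str):
        mutable = layout.mutable_parts
        if len(mutable) != 1:
            raise ValueError(
                "layout has multiple mutable parts; pass a name→sequence mapping"
            )
        transducer = {mutable[0].name: transducer}
    return RegazymeDesign(layout, dict(transducer))


def cleave(design: RegazymeDesign) -> tuple[str, str]:
    """Split the assembled RNA at the cleavage bond into (5', 3') fragments."""
    bond = design.cleavage_bond
    seed_start, _ = design.seed_interval
    if seed_start < bond:  # guarded already by layout validation
        raise ValueError("seed interval not fully on the 3' fragment")
    return design.assembled[:bond], design.assembled[bond:]


def random_transducer(bounds: tuple[int, int], rng: np.random.Generator) -> str:
    """Uniform-length, i.i.d.-uniform-base random transducer sequence."""
    lo, hi = bounds
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid bounds ({lo},{hi})")
    length = int(rng.integers(lo, hi + 1))
    return "".join(BASES[k] for k in rng.integers(0, 4, size=length))


def _feasible_moves(length: int, bounds: tuple[int, int]) -> set[str]:
    lo, hi = bounds
    moves = set()
    if length > 0:
        moves.add("substitution")
    if length < hi:
        moves.add("insertion")
    if length > lo:
        moves.add("deletion")
    return moves


def mutate(
    design: RegazymeDesign,
    rng: np.random.Generator,
    move_weights: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> RegazymeDesign:
    """Apply one random edit (substitution / insertion / deletion) to a transducer.

    Exactly one mutable part changes by exactly one edit; fixed parts are
    untouched.  Moves that would violate the length bounds are excluded
    before drawing; if no move is feasible a :class:`MoveError` is raised.
    """
    weights = np.asarray(move_weights, dtype=float)
    if weights.shape != (3,) or (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("move_weights must be three non-negative numbers, not all 0")
    weights = weights / weights.sum()

    mutable = design.layout.mutable_parts
    part = mutable[int(rng.integers(len(mutable)))] if len(mutable) > 1 else mutable[0]
    seq = design.transducers[part.name]
    feasible = _feasible_moves(len(seq), design.layout.transducer_length_bounds)
    probs = np.array(
        [weights[k] if MOVES[k] in feasible else 0.0 for k in range(3)]
    )
    if probs.sum() <= 0:
        raise MoveError(
            f"no feasible move for transducer {part.name!r} of length {len(seq)} "
            f"under weights {tuple(move_weights)}"
        )
    move = MOVES[int(rng.choice(3, p=probs / probs.sum()))]

    if move == "substitution":
        pos = int(rng.integers(len(seq)))
        new_base = BASES[int(rng.choice([k for k in range(4) if BASES[k] != seq[pos]]))]
        new_seq = seq[:pos] + new_base + seq[pos + 1 :]
    elif move == "insertion":
        pos = int(rng.integers(len(seq) + 1))
        new_seq = seq[:pos] + BASES[int(rng.integers(4))] + seq[pos:]
    else:  # deletion
        pos = int(rng.integers(len(seq)))
        new_seq = seq[:pos] + seq[pos + 1 :]

    new_tr = dict(design.transducers)
    new_tr[part.name] = new_seq
    return RegazymeDesign(design.layout, new_tr)
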