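"""Brute-force oracles kept independent of the package implementation.

Structure space is explored by naive recursive enumeration of all
non-crossing canonical pairings (no dynamic programming); the engine's
tie-break rule is replayed declaratively over the enumerated set.  These
oracles are exponential and only used on short sequences.
"""

from itertools import product

CAN = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_HAIRPIN = 3


def enumerate_structures(seq: str) -> list[frozenset[tuple[int, int]]]:
    """All valid structures of ``seq`` as sets of (i, j) pairs."""

    def rec(i: int, j: int) -> list[frozenset]:
        if j - i + 1 <= 0:
            return [frozenset()]
        out = []
        # position i unpaired
        out.extend(rec(i + 1, j))
        # position i paired to k
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if (seq[i], seq[k]) in CAN:
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return out

    return rec(0, len(seq) - 1)


def max_pair_count(seq: str) -> int:
    return max((len(s) for s in enumerate_structures(seq)), default=0)


def to_dotbracket(n: int, pairs) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def canonical_structure(seq: str) -> str:
    """The maximum-pairing structure selected by the declarative tie-break:
    scan 5'→3'; prefer paired over unpaired; then the 5'-most partner."""
    structs = enumerate_structures(seq)
    best = max((len(s) for s in structs), default=0)
    pool = [s for s in structs if len(s) == best]
    n = len(seq)
    for pos in range(n):
        if len(pool) == 1:
            break
        # positions closing an earlier pair are already decided (pool agrees)
        opening = [s for s in pool if any(i == pos for (i, _) in s)]
        closing = [s for s in pool if any(j == pos for (_, j) in s)]
        if closing and len(closing) == len(pool):
            continue
        if opening:
            kmin = min(j for s in opening for (i, j) in s if i == pos)
            pool = [s for s in opening if (pos, kmin) in s]
        else:
            pool = [s for s in pool if not any(j == pos for (_, j) in s)]
    return to_dotbracket(n, pool[0])


def all_sequences(length: int):
    for tup in product("ACGU", repeat=length):
        yield "".join(tup)


def oracle_score(design, weights=(1.0, 1.0, 1.0)):
    """Three penalty counts from enumerated structures of both states."""
    assembled = design.assembled
    bond = design.cleavage_bond
    frag = assembled[bond:]
    uncleaved = canonical_structure(assembled)
    fragment = canonical_structure(frag)
    a0, a1 = design.aptamer_interval
    target = design.layout.target_aptamer_structure
    d_apt = sum(
        x != y for x, y in zip(uncleaved[a0:a1], target)
    )
    s0, s1 = design.seed_interval
    d_seed_pre = uncleaved[s0:s1].count(".")
    d_seed_post = sum(c != "." for c in fragment[s0 - bond : s1 - bond])
    total = weights[0] * d_apt + weights[1] * d_seed_pre + weights[2] * d_seed_post
    return d_apt, d_seed_pre, d_seed_post, total
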