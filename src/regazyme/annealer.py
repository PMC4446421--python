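"""Monte Carlo simulated annealing over transducer sequence space.

The annealer minimises the three-term structural penalty by iterating
single-nucleotide moves (substitution, insertion, deletion) on the
transducer and accepting them with the Metropolis rule under a geometric
cooling schedule.  Score-neutral moves are always accepted, which lets the
walk drift across the large plateaus of equally good designs typical of
this objective.  All randomness flows from one seeded generator, so runs
are exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .folding import FoldingEngine, get_engine
from .objective import ScoreComponents, score_design
from .parts import RegazymeDesign, RegazymeLayout, assemble, mutate, random_transducer

__all__ = ["AnnealSchedule", "AnnealResult", "metropolis_accept", "anneal", "anneal_multi"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule and move configuration.

    Temperature is in score units; after every ``steps_per_stage``
    iterations it is multiplied by ``cooling_factor``.  The defaults solve
    the enumerable toy problems in well under a second.
    """

    T0: float = 5.0
    cooling_factor: float = 0.95
    steps_per_stage: int = 50
    max_iterations: int = 20_000
    stop_score: float = 0.0
    rng_seed: int = 0
    move_weights: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must lie in (0,1)")
        if self.steps_per_stage <= 0 or self.max_iterations <= 0:
            raise ValueError("step counts must be positive")


@dataclass
class AnnealResult:
    best: RegazymeDesign
    best_score: ScoreComponents
    trajectory: pd.DataFrame
    n_evaluations: int


def metropolis_accept(
    delta_score: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept with probability min(1, exp(-delta/T)); improvements and ties always."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_score <= 0:
        return True
    return rng.random() < math.exp(-delta_score / temperature)


def anneal(
    layout: RegazymeLayout,
    engine: FoldingEngine | str = "toy",
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    schedule: AnnealSchedule | None = None,
    *,
    initial_transducer: str | dict[str, str] | None = None,
) -> AnnealResult:
    """Minimise the penalty score over transducer sequences.

    Starts from ``initial_transducer`` (random under the layout bounds when
    omitted), runs at most ``schedule.max_iterations`` moves, and stops
    early when the best total reaches ``schedule.stop_score``.  Scores are
    memoized per transducer sequence; memoization changes call counts only,
    never results.
    """
    schedule = schedule or AnnealSchedule()
    eng = get_engine(engine)
    rng = np.random.default_rng(schedule.rng_seed)

    if initial_transducer is None:
        initial_transducer = {
            p.name: random_transducer(layout.transducer_length_bounds, rng)
            for p in layout.mutable_parts
        }
    current = assemble(layout, initial_transducer)

    cache: dict[tuple[str, ...], ScoreComponents] = {}
    n_eval = 0

    def scored(design: RegazymeDesign) -> ScoreComponents:
        nonlocal n_eval
        key = tuple(design.transducers[p.name] for p in layout.mutable_parts)
        if key not in cache:
            cache[key] = score_design(design, eng, weights)
            n_eval += 1
        return cache[key]

    cur_score = scored(current)
    best, best_score = current, cur_score

    records = []
    temperature = schedule.T0
    accepted_in_stage = 0
    iteration = 0
    while iteration < schedule.max_iterations and best_score.total > schedule.stop_score:
        iteration += 1
        candidate = mutate(current, rng, schedule.move_weights)
        cand_score = scored(candidate)
        if metropolis_accept(cand_score.total - cur_score.total, temperature, rng):
            current, cur_score = candidate, cand_score
            accepted_in_stage += 1
            if cur_score.total < best_score.total:
                best, best_score = current, cur_score
        records.append(
            (iteration, temperature, cur_score.total, best_score.total)
        )
        if iteration % schedule.steps_per_stage == 0:
            log.info(
                "stage end at iteration %d: T=%.4g best=%.4g acceptance=%.2f",
                iteration,
                temperature,
                best_score.total,
                accepted_in_stage / schedule.steps_per_stage,
            )
            temperature *= schedule.cooling_factor
            accepted_in_stage = 0

    trajectory = pd.DataFrame(
        records, columns=["iteration", "temperature", "current_score", "best_score"]
    )
    return AnnealResult(best, best_score, trajectory, n_eval)


def anneal_multi(
    layout: RegazymeLayout,
    n_runs: int,
    engine: FoldingEngine | str = "toy",
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    schedule: AnnealSchedule | None = None,
) -> list[AnnealResult]:
    """Independent restarts with distinct seeds, for consensus analysis."""
    schedule = schedule or AnnealSchedule()
    results = []
    for run in range(n_runs):
        run_schedule = AnnealSchedule(
            T0=schedule.T0,
            cooling_factor=schedule.cooling_factor,
            steps_per_stage=schedule.steps_per_stage,
            max_iterations=schedule.max_iterations,
            stop_score=schedule.stop_score,
            rng_seed=schedule.rng_seed + run,
            move_weights=schedule.move_weights,
        )
        results.append(anneal(layout, engine, weights, run_schedule))
    return results
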