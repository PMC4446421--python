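"""Synthetic fixtures: a toy design problem and synthetic measurement data.

``toy_layout`` is a miniature regazyme whose transducer space is fully
enumerable (bounds (3,3) → 64 candidates) and which is exactly solvable
under the deterministic maximum-pairing engine: the anti-seed transducer
CCC pairs the GGG seed in the uncleaved state, the 9-nt aptamer hairpin
folds to its target, and the released 3' fragment leaves the seed
single-stranded.  ``timecourse`` emits synthetic gel-quantification CSVs
at the characterization sampling times for the three reference
conditions; ``ensemble`` emits simulated single-cell reporter traces.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import cascade as casc
from .io import config_hash, write_layout, write_parts_fasta, write_timecourse_csv
from .kinetics import CHARACTERIZATION_TIMES, KineticsParams, simulate_timecourse
from .parts import Part, RegazymeLayout, RegionRef

__all__ = ["toy_layout", "REFERENCE_KINETICS", "make_fixtures"]


def toy_layout(bounds: tuple[int, int] = (3, 3)) -> RegazymeLayout:
    """The enumerable toy design problem (optimum score 0 at transducer CCC)."""
    parts = (
        Part("transducer", "transducer", "AAA", mutable=True),
        Part("aptamer", "aptamer", "GCGAAACGC"),
        Part("riboregulator", "riboregulator", "GGGAA"),
    )
    return RegazymeLayout(
        parts=parts,
        cleavage_after="transducer",
        seed=RegionRef("riboregulator", 0, 3),
        target_aptamer_structure="(((...)))",
        transducer_length_bounds=bounds,
    )


#: reference kinetic conditions used for characterization: label →
#: (params, noise sd) with rates and fractions as measured for each construct
REFERENCE_KINETICS: dict[str, tuple[KineticsParams, float]] = {
    "theoHHAzRAJ12_4mM": (KineticsParams(f0=0.30, fmax=0.80, lam=0.15, m=1.0), 0.05),
    "theoHHAzRAJ12_0.4mM": (KineticsParams(f0=0.30, fmax=0.80, lam=1.5, m=1.0), 0.05),
    "breakHHRzRAJ12_100ngml": (KineticsParams(f0=0.01, fmax=0.25, lam=0.17, m=2.0), 0.02),
}


def make_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Write fixture files of the requested kind; byte-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    if kind == "toy_layout":
        layout = toy_layout()
        parts_path = outdir / "parts.fasta"
        layout_path = outdir / "layout.yaml"
        write_parts_fasta(list(layout.parts), parts_path)
        write_layout(layout, layout_path)
        written += [parts_path, layout_path]
    elif kind == "timecourse":
        for label, (params, noise_sd) in REFERENCE_KINETICS.items():
            courses = [
                simulate_timecourse(
                    params, CHARACTERIZATION_TIMES, noise_sd, rng, replicate=f"r{k}"
                )
                for k in range(3)
            ]
            path = outdir / f"timecourse_{label}.csv"
            write_timecourse_csv(courses, path, seed=seed)
            written.append(path)
    elif kind == "ensemble":
        params = casc.CascadeParams()
        profile = casc.build_signal_profile("step", level=25.0, t_on=7.0)
        t = np.linspace(0.0, 120.0, 121)
        cells = casc.single_cell_ensemble(
            params, profile, t, n_cells=20, extrinsic_cv=0.2, rng=rng
        )
        rows = []
        for cid, traj in enumerate(cells):
            for k in range(t.size):
                rows.append(
                    {
                        "time": traj.t[k],
                        "cell_id": cid,
                        "Ru": traj.Ru[k],
                        "Ra": traj.Ra[k],
                        "G": traj.G[k],
                    }
                )
        path = outdir / "ensemble.csv"
        with open(path, "w") as fh:
            fh.write(f"# regazyme seed={seed} config={config_hash({'kind': kind})}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
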