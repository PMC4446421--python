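"""File formats: parts FASTA, layout config, dot-bracket, design reports.

Parts travel as FASTA with the role (and mutability) encoded in the
description line (``role=aptamer mutable=false``); layouts as small YAML
documents; structures as Vienna-style dot-bracket files (sequence line,
structure line with the energy in trailing parentheses); tabular results
as CSV with a ``#`` provenance header carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .folding import FoldResult
from .objective import ScoreComponents
from .parts import Part, RegazymeDesign, RegazymeLayout, RegionRef

__all__ = [
    "read_parts_fasta",
    "write_parts_fasta",
    "read_layout",
    "write_layout",
    "write_dotbracket",
    "read_dotbracket",
    "write_design_report",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "config_hash",
]

FASTA_WIDTH = 60


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping (for provenance lines)."""
    blob = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def read_parts_fasta(path) -> list[Part]:
    """Parse parts from FASTA; role tags live in the description line."""
    parts = []
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        tags = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        if "role" not in tags:
            raise ValueError(f"record {rec.id!r} (#{k}) lacks a role=... tag")
        mutable = tags.get("mutable", "false").lower() in ("true", "1", "yes")
        try:
            parts.append(
                Part(rec.id, tags["role"], str(rec.seq), mutable=mutable)
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r} (#{k}): {exc}") from exc
    return parts


def write_parts_fasta(parts: list[Part], path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.name,
            description=f"role={p.role} mutable={'true' if p.mutable else 'false'}",
        )
        for p in parts
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_layout(path, parts: list[Part]) -> RegazymeLayout:
    """Build a layout from a YAML config plus the parts it references."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    by_name = {p.name: p for p in parts}
    try:
        order = cfg["order"]
        missing = [n for n in order if n not in by_name]
        if missing:
            raise ValueError(f"layout references unknown parts {missing}")
        seed = cfg["seed"]
        apt = cfg.get("aptamer")
        bounds = cfg.get("transducer_length_bounds", {"min": 0, "max": 30})
        return RegazymeLayout(
            parts=tuple(by_name[n] for n in order),
            cleavage_after=cfg["cleavage_after"],
            seed=RegionRef(seed["part"], int(seed["start"]), int(seed["end"])),
            aptamer=(
                RegionRef(apt["part"], int(apt["start"]), int(apt["end"]))
                if apt
                else None
            ),
            target_aptamer_structure=cfg["target_aptamer_structure"],
            transducer_length_bounds=(int(bounds["min"]), int(bounds["max"])),
        )
    except KeyError as exc:
        raise ValueError(f"layout config missing key {exc}") from exc


def layout_config(layout: RegazymeLayout) -> dict:
    lo, hi = layout.transducer_length_bounds
    return {
        "order": [p.name for p in layout.parts],
        "cleavage_after": layout.cleavage_after,
        "seed": {
            "part": layout.seed.part,
            "start": layout.seed.start,
            "end": layout.seed.end,
        },
        "aptamer": {
            "part": layout.aptamer.part,
            "start": layout.aptamer.start,
            "end": layout.aptamer.end,
        },
        "target_aptamer_structure": layout.target_aptamer_structure,
        "transducer_length_bounds": {"min": lo, "max": hi},
    }


def write_layout(layout: RegazymeLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_config(layout), fh, sort_keys=False)


def write_dotbracket(folds: list[tuple[str, FoldResult]], path) -> None:
    """Vienna layout: '>name', sequence line, structure line with energy."""
    with open(path, "w") as fh:
        for name, fold in folds:
            fh.write(f">{name}\n{fold.sequence}\n{fold.structure} ({fold.energy:.2f})\n")


def read_dotbracket(path) -> list[tuple[str, FoldResult]]:
    out = []
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    for k in range(0, len(lines), 3):
        name = lines[k].lstrip(">")
        seq = lines[k + 1]
        struct, _, energy = lines[k + 2].rpartition(" (")
        out.append((name, FoldResult(seq, struct, float(energy.rstrip(")")))))
    return out


def _provenance_line(seed, cfg_hash) -> str:
    return f"# regazyme seed={seed} config={cfg_hash}\n"


def write_design_report(
    designs: list[RegazymeDesign],
    scores: list[ScoreComponents],
    outdir,
    engine="toy",
    seed: int = 0,
) -> dict[str, Path]:
    """FASTA of assembled designs, CSV of score components, dot-bracket files."""
    from .folding import get_engine
    from .parts import cleave

    if len(designs) != len(scores):
        raise ValueError("designs and scores must have equal length")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eng = get_engine(engine)
    cfg = config_hash(
        layout_config(designs[0].layout) if designs else {"empty": True}
    )

    fasta = outdir / "designs.fasta"
    records = [
        SeqRecord(
            Seq(d.assembled),
            id=f"design_{k}",
            description=f"transducer={d.transducer_sequence} seed={seed} config={cfg}",
        )
        for k, d in enumerate(designs)
    ]
    with open(fasta, "w") as fh:
        SeqIO.write(records, fh, "fasta")

    csv = outdir / "scores.csv"
    rows = [
        {
            "design_id": f"design_{k}",
            "transducer": d.transducer_sequence,
            "d_apt": s.d_apt,
            "d_seed_pre": s.d_seed_pre,
            "d_seed_post": s.d_seed_post,
            "total": s.total,
            "mfe_uncleaved": s.mfe_uncleaved,
            "mfe_fragment": s.mfe_fragment,
        }
        for k, (d, s) in enumerate(zip(designs, scores))
    ]
    columns = [
        "design_id", "transducer", "d_apt", "d_seed_pre", "d_seed_post",
        "total", "mfe_uncleaved", "mfe_fragment",
    ]
    with open(csv, "w") as fh:
        fh.write(_provenance_line(seed, cfg))
        pd.DataFrame(rows, columns=columns).to_csv(fh, index=False)

    dbn = outdir / "structures.dbn"
    folds = []
    for k, d in enumerate(designs):
        folds.append((f"design_{k}_uncleaved", eng.mfe_fold(d.assembled)))
        folds.append((f"design_{k}_fragment3p", eng.mfe_fold(cleave(d)[1])))
    write_dotbracket(folds, dbn)
    return {"fasta": fasta, "csv": csv, "dbn": dbn}


def write_timecourse_csv(courses, path, seed: int = 0) -> None:
    """Time courses as CSV (time_min, fraction, replicate)."""
    rows = []
    for course in courses:
        for t, f in zip(course.times, course.fractions):
            rows.append(
                {"time_min": t, "fraction": f, "replicate": course.replicate or ""}
            )
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, config_hash({"kind": "timecourse"})))
        pd.DataFrame(rows, columns=["time_min", "fraction", "replicate"]).to_csv(
            fh, index=False
        )


def read_timecourse_csv(path):
    """Read (time_min, fraction[, replicate]) CSV into TimeCourse objects."""
    from .kinetics import TimeCourse

    df = pd.read_csv(path, comment="#")
    if "replicate" not in df.columns:
        df["replicate"] = ""
    df["replicate"] = df["replicate"].fillna("")
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            TimeCourse(
                tuple(grp["time_min"]), tuple(grp["fraction"]), str(rep) or None
            )
        )
    return out
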