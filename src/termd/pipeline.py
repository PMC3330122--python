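"""End-to-end pipeline: classify → simulate → statistics → report.

Runs the packaged strain panel through the rule engine, checks it against the
expectation table, simulates mobility and segregation for the wild type and
writes summary tables.  Used by the ``termd run`` CLI command; importable for
scripted use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fixtures import MARKER_POSITIONS, expected_class_records, strain_panel
from .insulation import CellCycleStage, MobilityClass, classify_marker
from .simulate import (DEFAULT_COHESION, DEFAULT_GROWTH, DEFAULT_MOTION,
                       SimConfig, cooper_copy_number, population_for_strain,
                       simulate_trajectories)
from .stats import coloc_index, summarize_group, travelled_distance

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    n_cells: int = 1000
    n_foci: int = 30
    strains: list[str] | None = None  # default: full panel
    extra: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the report dict (also written as JSON).

    The report compares computed classes to the packaged expectations and
    summarises the simulated mobility/segregation statistics; ``mismatches``
    is 0 on a healthy install.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = strain_panel()
    if config.strains:
        panel = {k: v for k, v in panel.items() if k in config.strains}

    # 1. classification vs expectations
    expected = expected_class_records()
    rows, mismatches = [], 0
    for rec in expected:
        if rec["strain"] not in panel:
            continue
        strain = panel[rec["strain"]]
        got = classify_marker(strain, rec["marker"],
                              CellCycleStage(rec["stage"])).value
        ok = got == rec["expected_class"]
        mismatches += 0 if ok else 1
        rows.append({**rec, "computed_class": got, "agrees": ok})
    classes = pd.DataFrame(rows)
    classes.to_csv(out / "class_report.tsv", sep="\t", index=False)

    # 2. mobility simulation per class
    cfg = SimConfig(seed=config.seed, n_foci=config.n_foci)
    mobility = []
    for i, (mclass, mp) in enumerate(DEFAULT_MOTION.items()):
        trajs = simulate_trajectories(mp, cfg, seed=config.seed + i)
        g = summarize_group([travelled_distance(t) for t in trajs],
                            expected_n=config.n_foci)
        mobility.append({"class": mclass.value, "n": g.n,
                         "mean_travelled_um": g.mean, "sd_um": g.sd})
    mob = pd.DataFrame(mobility)
    mob.to_csv(out / "mobility_summary.tsv", sep="\t", index=False)

    # 3. co-localization index for the wild type marker set
    wt = panel.get("wt") or strain_panel()["wt"]
    sample, pms = population_for_strain(
        wt, list(MARKER_POSITIONS), growth=DEFAULT_GROWTH,
        cohesion=DEFAULT_COHESION, n_cells=config.n_cells, seed=config.seed)
    coloc = []
    for name, pm in pms.items():
        nb_th = cooper_copy_number(pm.m_rel, DEFAULT_GROWTH)
        nb_obs = sample.mean_focus_count(name)
        coloc.append({"marker": name, "class": pm.mclass.value,
                      "m_rel": round(pm.m_rel, 4), "nb_th": round(nb_th, 4),
                      "nb_obs": round(nb_obs, 4),
                      "index": round(coloc_index(nb_th, nb_obs), 4)})
    coloc_df = pd.DataFrame(coloc)
    coloc_df.to_csv(out / "coloc_summary.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_class_rows": len(rows),
        "mismatches": mismatches,
        "spread_empty_everywhere": bool(
            classes.empty or not (classes["computed_class"] == "CONSTRAINED").any()
        ),
        "mobility": mobility,
        "coloc": coloc,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
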