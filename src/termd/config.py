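"""Strain configuration files (YAML/JSON) and fixture generation.

A strain config holds everything the rule engine and simulator need: genome
length, the region tiling, point features (markers, insulators with their
12-bp sequences, oriC/dif) and the genotype flags.  Unknown keys are rejected
with their location so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .genome import CircularGenome, Feature, GenomeError, Region
from .insulation import Genotype, StrainModel

__all__ = ["strain_to_dict", "strain_from_dict", "load_strain_config",
           "save_strain_config", "generate_fixtures", "file_sha256"]

_GENOTYPE_KEYS = {"matP", "zapB", "yfbV", "yihI"}
_REGION_KEYS = {"label", "start_bp", "end_bp", "source", "orig_start_bp",
                "orig_end_bp", "orient", "note"}
_FEATURE_KEYS = {"name", "kind", "position_bp", "strand", "sequence"}
_GENOME_KEYS = {"length_bp", "regions", "features"}
_TOP_KEYS = {"name", "genome", "genotype"}


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise GenomeError(f"unknown key(s) {sorted(unknown)} in {where}")


def strain_to_dict(strain: StrainModel) -> dict:
    g = strain.genome
    return {
        "name": strain.name,
        "genome": {
            "length_bp": g.length_bp,
            "regions": [
                {k: v for k, v in {
                    "label": r.label, "start_bp": r.start_bp, "end_bp": r.end_bp,
                    "source": r.source, "orig_start_bp": r.orig_start_bp,
                    "orig_end_bp": r.orig_end_bp,
                    "orient": r.orient if r.orient != 1 else None,
                }.items() if v is not None}
                for r in g.ordered_regions()
            ],
            "features": [
                {k: v for k, v in {
                    "name": f.name, "kind": f.kind, "position_bp": f.position_bp,
                    "strand": f.strand if f.strand != "." else None,
                    "sequence": f.sequence,
                }.items() if v is not None}
                for f in sorted(g.features, key=lambda f: (f.position_bp, f.name))
            ],
        },
        "genotype": {
            "matP": strain.genotype.matP, "zapB": strain.genotype.zapB,
            "yfbV": strain.genotype.yfbV, "yihI": strain.genotype.yihI,
        },
    }


def strain_from_dict(d: dict, where: str = "<config>") -> StrainModel:
    if not isinstance(d, dict):
        raise GenomeError(f"{where}: expected a mapping at top level")
    _check_keys(d, _TOP_KEYS, where)
    for key in ("name", "genome", "genotype"):
        if key not in d:
            raise GenomeError(f"{where}: missing required key {key!r}")
    gd = d["genome"]
    _check_keys(gd, _GENOME_KEYS, f"{where}:genome")
    if "length_bp" not in gd or "regions" not in gd:
        raise GenomeError(f"{where}:genome needs length_bp and regions")
    regions = []
    for i, rd in enumerate(gd["regions"]):
        _check_keys(rd, _REGION_KEYS, f"{where}:genome.regions[{i}]")
        regions.append(Region(**rd))
    features = []
    for i, fd in enumerate(gd.get("features", [])):
        _check_keys(fd, _FEATURE_KEYS, f"{where}:genome.features[{i}]")
        features.append(Feature(**fd))
    genome = CircularGenome(d["name"], int(gd["length_bp"]), regions, features)
    gt = d["genotype"]
    _check_keys(gt, _GENOTYPE_KEYS, f"{where}:genotype")
    missing = {"matP", "zapB", "yfbV"} - set(gt)
    if missing:
        raise GenomeError(f"{where}:genotype missing flag(s) {sorted(missing)}")
    genotype = Genotype(**{k: bool(v) for k, v in gt.items()})
    return StrainModel(genome=genome, genotype=genotype, name=d["name"])


def load_strain_config(path: str | Path) -> StrainModel:
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text))
    return strain_from_dict(data, where=str(path))


def save_strain_config(strain: StrainModel, path: str | Path) -> None:
    path = Path(path)
    d = strain_to_dict(strain)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def generate_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the packaged fixture set into ``outdir``.

    Emits the full strain panel as YAML configs, the expected-class table as
    TSV, a planted-motif FASTA, and seeded synthetic trajectory/population
    datasets for the wild type.  Regeneration with the same seed is
    bit-identical.
    """
    import pandas as pd

    from .fixtures import (MARKER_POSITIONS, expected_class_records,
                           planted_motif_fasta, strain_panel)
    from .simulate import (DEFAULT_COHESION, DEFAULT_GROWTH, DEFAULT_MOTION,
                           SimConfig, population_for_strain,
                           simulate_trajectories)
    from .stats import write_trajectories_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    strain_dir = outdir / "strains"
    strain_dir.mkdir(exist_ok=True)
    for name, strain in strain_panel().items():
        p = strain_dir / f"{name.replace('+', '_')}.yaml"
        save_strain_config(strain, p)
        written[f"strain:{name}"] = p

    p = outdir / "expected_classes.tsv"
    pd.DataFrame(expected_class_records()).to_csv(p, sep="\t", index=False)
    written["expected_classes"] = p

    seq, plants = planted_motif_fasta(seed=seed)
    p = outdir / "planted_motifs.fasta"
    with open(p, "w") as fh:
        fh.write(f">planted seed={seed} sites=" +
                 ",".join(f"{pos}:{site}" for pos, site in sorted(plants.items()))
                 + "\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    written["planted_fasta"] = p

    wt = strain_panel()["wt"]
    cfg = SimConfig(seed=seed)
    trajs = []
    for offset, (cls_name, mclass) in enumerate(
            (("free", "FREE"), ("ter", "TER_ANCHORED")), start=1):
        from .insulation import MobilityClass
        mp = DEFAULT_MOTION[MobilityClass[mclass]]
        trajs.extend(simulate_trajectories(mp, cfg, n=cfg.n_foci,
                                           seed=seed + offset,
                                           locus_id=cls_name))
    p = outdir / "wt_trajectories.tsv"
    write_trajectories_tsv(trajs, p, header_meta={
        "version": __version__, "seed": seed})
    written["trajectories"] = p

    sample, _ = population_for_strain(
        wt, list(MARKER_POSITIONS), growth=DEFAULT_GROWTH,
        cohesion=DEFAULT_COHESION, n_cells=500, seed=seed)
    p = outdir / "wt_population.tsv"
    sample.to_tsv(p)
    written["population"] = p
    return written
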