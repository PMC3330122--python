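"""Packaged study fixtures: reference genome, strain panel, expectation table.

The wild-type genome reconstructs the E. coli K-12 MG1655 map at macrodomain
resolution: four macrodomains (Ori, Right, Ter, Left) and the two
non-structured regions (NSR, NSL), the tidR/tidL insulators, oriC and dif,
and the fluorescent parS markers used to read out mobility.  Region borders
and marker coordinates away from the engineered att sites are best-effort
reconstructions from the published genetic maps (the primary literature does
not restate them all); they are configurable, and the strain panel only
depends on their relative order.

``STRAINS`` builds the full panel: seven att-defined transposition strains,
one inversion strain, insulator/gene deletions and the ectopic-insulator
insertions.  ``EXPECTED_CLASSES`` transcribes the observed mobility phenotype
of every informative strain × marker × stage combination into the discrete
class vocabulary of :mod:`termd.insulation`; the rule engine is required to
reproduce it exactly.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .genome import CircularGenome, Feature, Region, invert, transpose
from .insulation import CellCycleStage, Genotype, StrainModel
from .motifs import SHUFFLED_CONTROL, TIDL_SEQ, TIDR_SEQ

__all__ = [
    "GENOME_LENGTH", "WT_BORDERS", "MARKER_POSITIONS", "TIDR_POS", "TIDL_POS",
    "ORIC_POS", "DIF_POS", "ECTOPIC_SITE",
    "wt_genome", "build_strain", "strain_panel", "table1_strains",
    "EXPECTED_CLASSES", "expected_class_records", "planted_motif_fasta",
]

GENOME_LENGTH = 4_641_652  # E. coli K-12 MG1655

#: region borders (label owns the ascending half-open arc up to its value)
WT_BORDERS = {
    "Ori": (3_697_780, 130_000),   # wraps through the origin
    "NSR": (130_000, 600_000),
    "Right": (600_000, 1_135_000),
    "Ter": (1_135_000, 1_920_110),
    "Left": (1_920_110, 2_892_861),
    "NSL": (2_892_861, 3_697_780),
}

TIDR_POS = 1_000_000   # 3' end of ssuC, inside the 993-1002 kb insulation region
TIDL_POS = 1_966_000   # inside tar, ~46 kb left of the Ter border
ORIC_POS = 3_925_744
DIF_POS = 1_588_773
ECTOPIC_SITE = 320_000  # ykgC-ykgD intergene, between NSR-2 and NSR-5

MARKER_POSITIONS = {
    "Ori-3": 4_100_000,
    "NSR-1": 140_000,
    "NSR-2": 280_000,
    "NSR-5": 480_000,
    "Right-2": 750_000,
    "Right-5": 920_000,
    "Ter-3": 1_600_000,
    "Left-2": 2_100_000,
    "Left-1": 2_400_000,
    "NSL-3": 3_100_000,
    "NSL-4": 3_400_000,
}

#: Table 1 att coordinates: strain -> (attL, attR, attB')
TABLE1 = {
    "LC13-R127-BO-NSR": (1_099_533, 651_775, 153_248),
    "LR146-R124-BL-T2": (3_697_780, 2_892_861, 1_920_110),
    "LR14-R127-BO-NSR": (914_188, 651_775, 153_248),
    "LC13-R17-BO-NSR": (1_099_533, 806_540, 153_248),
    "LR132-R127-BO-NSR": (993_242, 651_775, 153_248),
    "LR128-R127-BO-NSR": (1_002_340, 651_775, 153_248),
    "LR146-R124-BL-T": (3_697_780, 2_892_861, 2_202_349),
}

#: printed post-transposition configurations for the Table 1 strains
TABLE1_CONFIGURATIONS = {
    "LC13-R127-BO-NSR": "Ori-Right-NSR-Ter-Left-NSL",
    "LR146-R124-BL-T2": "Ori-NSR-Right-Ter-NSL-Left",
    "LR14-R127-BO-NSR": "Ori-Right(651-914)-NSR-Right(914-1135)-Ter-Left-NSL",
    "LC13-R17-BO-NSR": "Ori-Right(806-1099)-NSR-Right(600-806)-Ter-Left-NSL",
    "LR132-R127-BO-NSR": "Ori-Right(651-993)-NSR-Right(993-1135)-Ter-Left-NSL",
    "LR128-R127-BO-NSR": "Ori-Right(651-1002)-NSR-Right(1002-1135)-Ter-Left-NSL",
    "LR146-R124-BL-T": "Ori-NSR-Right-Ter-Left(1920-2202)-NSL-Left(2202-2892)",
}

INVERSION_STRAIN = "LC13-R524"
INVERSION_SITES = (1_005_000, 2_055_000)  # Right MD site, Left MD site


def wt_genome(name: str = "wt") -> CircularGenome:
    regions = [
        Region(label, start_bp=s, end_bp=e) for label, (s, e) in WT_BORDERS.items()
    ]
    features = [
        Feature(n, "marker", p) for n, p in MARKER_POSITIONS.items()
    ] + [
        Feature("tidR", "insulator", TIDR_POS, "+", TIDR_SEQ),
        Feature("tidL", "insulator", TIDL_POS, "+", TIDL_SEQ),
        Feature("oriC", "gene", ORIC_POS),
        Feature("dif", "gene", DIF_POS),
    ]
    return CircularGenome(name, GENOME_LENGTH, regions, features)


def build_strain(name: str) -> StrainModel:
    """Build any strain of the packaged panel by name.

    Names compose: a base (``wt``, a Table 1 strain, or ``LC13-R524``) plus
    ``+d<gene>`` deletion suffixes and ``+ect_<tidR|tidL|shuffled>`` ectopic
    insulator insertions, e.g. ``"dtidR+dzapB"`` or ``"dtidR+ect_tidL"``.
    """
    parts = name.split("+")
    base = parts[0]
    mods = parts[1:]
    genome = wt_genome(name)
    if base in TABLE1:
        attL, attR, attB2 = TABLE1[base]
        genome, _ = transpose(genome, attL, attR, attB2)
        genome.name = name
    elif base == INVERSION_STRAIN:
        genome, _ = invert(genome, *INVERSION_SITES)
        genome.name = name
    elif base != "wt":
        mods = parts  # base itself is a modifier on wt (e.g. "dtidR")
    genotype = Genotype()
    for mod in mods:
        if mod in {"dtidR", "drins2"}:
            # rins deletions remove the tidR palindrome; modelled as feature
            # removal (kb-scale deletions are negligible on the MD map)
            genome.features = [f for f in genome.features if f.name != "tidR"]
        elif mod == "dmatP":
            genotype = replace(genotype, matP=False)
        elif mod == "dzapB":
            genotype = replace(genotype, zapB=False)
        elif mod == "dyfbV":
            genotype = replace(genotype, yfbV=False)
        elif mod == "dyihI":
            genotype = replace(genotype, yihI=False)
        elif mod.startswith("ect_"):
            seq = {"tidR": TIDR_SEQ, "rins2.1": TIDR_SEQ, "tidL": TIDL_SEQ,
                   "shuffled": SHUFFLED_CONTROL}[mod[4:]]
            genome.features.append(
                Feature(f"{mod[4:]}@ykgCD", "insulator", ECTOPIC_SITE, "+", seq))
        else:
            raise ValueError(f"unknown strain modifier {mod!r} in {name!r}")
    return StrainModel(genome=genome, genotype=genotype, name=name)


#: the full packaged panel
PANEL = (
    ["wt"] + list(TABLE1) + [INVERSION_STRAIN] + [
        "dtidR", "dtidR+dzapB", "dzapB", "dmatP", "dyfbV", "dyfbV+dmatP",
        "LC13-R127-BO-NSR+dmatP",
        "dtidR+ect_rins2.1", "dtidR+ect_tidL", "dtidR+ect_shuffled",
    ]
)


def strain_panel() -> dict[str, StrainModel]:
    return {name: build_strain(name) for name in PANEL}


def table1_strains() -> dict[str, StrainModel]:
    return {name: build_strain(name) for name in TABLE1}


_A = CellCycleStage.ANCHORED.value
_P = CellCycleStage.PRE_ANCHORING.value

#: (strain, marker, stage, expected class, provenance figure panel)
EXPECTED_CLASSES: list[tuple[str, str, str, str, str]] = [
    # wild type, anchored stage
    ("wt", "Ori-3", _A, "STRUCTURED", "Fig2A"),
    ("wt", "NSR-1", _A, "FREE", "Fig2A"),
    ("wt", "NSR-2", _A, "FREE", "Fig2A"),
    ("wt", "NSR-5", _A, "FREE", "Fig2A"),
    ("wt", "Right-2", _A, "STRUCTURED", "Fig2A"),
    ("wt", "Right-5", _A, "STRUCTURED", "Fig2A"),
    ("wt", "Ter-3", _A, "TER_ANCHORED", "Fig2A"),
    ("wt", "Left-1", _A, "STRUCTURED", "Fig2A"),
    ("wt", "Left-2", _A, "STRUCTURED", "Fig2A"),
    ("wt", "NSL-3", _A, "FREE", "Fig2A"),
    ("wt", "NSL-4", _A, "FREE", "Fig2A"),
    # NSR transposed next to Ter (Right MD moved out of the way)
    ("LC13-R127-BO-NSR", "Ori-3", _A, "STRUCTURED", "Fig2B"),
    ("LC13-R127-BO-NSR", "NSR-1", _A, "FREE", "Fig2B"),
    ("LC13-R127-BO-NSR", "Right-2", _A, "STRUCTURED", "Fig2B"),
    ("LC13-R127-BO-NSR", "Right-5", _A, "STRUCTURED", "Fig2B"),
    ("LC13-R127-BO-NSR", "NSR-2", _A, "CONSTRAINED", "Fig2B"),
    ("LC13-R127-BO-NSR", "NSR-5", _A, "CONSTRAINED", "Fig2B"),
    ("LC13-R127-BO-NSR", "Ter-3", _A, "TER_ANCHORED", "Fig2B"),
    ("LC13-R127-BO-NSR", "Left-1", _A, "STRUCTURED", "Fig2B"),
    ("LC13-R127-BO-NSR", "NSL-3", _A, "FREE", "Fig2B"),
    ("LC13-R127-BO-NSR", "NSL-4", _A, "FREE", "Fig2B"),
    # NSL transposed next to Ter
    ("LR146-R124-BL-T2", "Ori-3", _A, "STRUCTURED", "Fig2C"),
    ("LR146-R124-BL-T2", "NSR-2", _A, "FREE", "Fig2C"),
    ("LR146-R124-BL-T2", "Ter-3", _A, "TER_ANCHORED", "Fig2C"),
    ("LR146-R124-BL-T2", "NSL-3", _A, "CONSTRAINED", "Fig2C"),
    ("LR146-R124-BL-T2", "Left-1", _A, "STRUCTURED", "Fig2C"),
    # matP deletion in the transposed background releases everything Ter-borne
    ("LC13-R127-BO-NSR+dmatP", "Ori-3", _A, "STRUCTURED", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "NSR-1", _A, "FREE", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "Right-2", _A, "STRUCTURED", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "Right-5", _A, "STRUCTURED", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "NSR-2", _A, "FREE", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "NSR-5", _A, "FREE", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "Ter-3", _A, "FREE", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "Left-1", _A, "STRUCTURED", "Fig2E"),
    ("LC13-R127-BO-NSR+dmatP", "NSL-4", _A, "FREE", "Fig2E"),
    # deletion mapping of the right-arm insulation determinant (Fig 3A)
    ("LR14-R127-BO-NSR", "NSR-2", _A, "FREE", "Fig3A"),       # 914-1135 kb kept
    ("LC13-R17-BO-NSR", "NSR-2", _A, "CONSTRAINED", "Fig3A"),  # 600-806 kb kept
    ("LR132-R127-BO-NSR", "NSR-2", _A, "FREE", "Fig3A"),      # 993-1135 kb kept
    ("LR128-R127-BO-NSR", "NSR-2", _A, "CONSTRAINED", "Fig3A"),  # 1002-1135 kb
    # tidR deletion in the native configuration
    ("dtidR", "NSR-2", _A, "CONSTRAINED", "Fig3D"),
    ("dtidR", "NSR-5", _A, "CONSTRAINED", "Fig3D"),
    ("dtidR", "Right-2", _A, "CONSTRAINED", "Fig3D"),
    ("dtidR", "NSL-4", _A, "FREE", "Fig3D"),
    # NSL transposed inside the Left MD: tidL-containing 282 kb stays Ter-proximal
    ("LR146-R124-BL-T", "NSR-2", _A, "FREE", "Fig3E"),
    ("LR146-R124-BL-T", "NSL-3", _A, "FREE", "Fig3E"),
    ("LR146-R124-BL-T", "NSL-4", _A, "FREE", "Fig3E"),
    ("LR146-R124-BL-T", "Left-1", _A, "STRUCTURED", "Fig3E"),
    # Right/Left inversion: the tidL-proximal 135 kb lands next to the Right MD
    ("LC13-R524", "NSR-2", _A, "FREE", "Fig3F"),
    # ectopic insulators in the middle of NSR (dtidR background)
    ("dtidR+ect_rins2.1", "NSR-2", _A, "FREE", "Fig4A"),
    ("dtidR+ect_rins2.1", "NSR-5", _A, "CONSTRAINED", "Fig4A"),
    ("dtidR+ect_rins2.1", "Right-2", _A, "CONSTRAINED", "Fig4A"),
    ("dtidR+ect_rins2.1", "NSL-4", _A, "FREE", "Fig4A"),
    ("dtidR+ect_tidL", "NSR-2", _A, "FREE", "Fig4B"),
    ("dtidR+ect_tidL", "NSR-5", _A, "CONSTRAINED", "Fig4B"),
    ("dtidR+ect_tidL", "NSL-4", _A, "FREE", "Fig4B"),
    ("dtidR+ect_shuffled", "NSR-2", _A, "CONSTRAINED", "Fig4C"),
    ("dtidR+ect_shuffled", "NSR-5", _A, "CONSTRAINED", "Fig4C"),
    ("dtidR+ect_shuffled", "NSL-4", _A, "FREE", "Fig4C"),
    # yfbV deletion: both NS regions constrained, MD and Ter markers unchanged
    ("dyfbV", "Ori-3", _A, "STRUCTURED", "Fig5A"),
    ("dyfbV", "NSR-2", _A, "CONSTRAINED", "Fig5A"),
    ("dyfbV", "Right-2", _A, "CONSTRAINED", "Fig5A"),
    ("dyfbV", "Ter-3", _A, "TER_ANCHORED", "Fig5A"),
    ("dyfbV", "Left-1", _A, "CONSTRAINED", "Fig5A"),
    ("dyfbV", "NSL-4", _A, "CONSTRAINED", "Fig5A"),
    # yfbV matP double mutant: constraining gone with MatP
    ("dyfbV+dmatP", "Ori-3", _A, "STRUCTURED", "Fig5B"),
    ("dyfbV+dmatP", "NSR-2", _A, "FREE", "Fig5B"),
    ("dyfbV+dmatP", "Right-2", _A, "STRUCTURED", "Fig5B"),
    ("dyfbV+dmatP", "Ter-3", _A, "FREE", "Fig5B"),
    ("dyfbV+dmatP", "Left-1", _A, "STRUCTURED", "Fig5B"),
    ("dyfbV+dmatP", "NSL-4", _A, "FREE", "Fig5B"),
    # zapB deletion: Ter released from the divisome, no spread
    ("dzapB", "Ori-3", _A, "STRUCTURED", "Fig6A"),
    ("dzapB", "NSR-2", _A, "FREE", "Fig6A"),
    ("dzapB", "Right-2", _A, "STRUCTURED", "Fig6A"),
    ("dzapB", "Ter-3", _A, "TER_STRUCTURED", "Fig6A"),
    ("dzapB", "Left-2", _A, "STRUCTURED", "Fig6A"),
    ("dzapB", "Left-1", _A, "STRUCTURED", "Fig6A"),
    # zapB + tidR double: removing the insulator has no effect without anchoring
    ("dtidR+dzapB", "Ori-3", _A, "STRUCTURED", "Fig6B"),
    ("dtidR+dzapB", "NSR-2", _A, "FREE", "Fig6B"),
    ("dtidR+dzapB", "NSR-5", _A, "FREE", "Fig6B"),
    ("dtidR+dzapB", "Right-2", _A, "STRUCTURED", "Fig6B"),
    # small cells, before the Ter MD reaches mid-cell
    ("wt", "Ori-3", _P, "STRUCTURED", "Fig6C"),
    ("wt", "NSR-5", _P, "FREE", "Fig6C"),
    ("wt", "Right-2", _P, "STRUCTURED", "Fig6C"),
    ("wt", "Ter-3", _P, "TER_STRUCTURED", "Fig6C"),
    ("dtidR", "Ori-3", _P, "STRUCTURED", "Fig6D"),
    ("dtidR", "NSR-2", _P, "FREE", "Fig6D"),
    ("dtidR", "NSR-5", _P, "FREE", "Fig6D"),
    ("dtidR", "Right-2", _P, "STRUCTURED", "Fig6D"),
    ("dtidR", "Ter-3", _P, "TER_STRUCTURED", "Fig6D"),
    ("dtidR", "NSL-4", _P, "FREE", "Fig6D"),
]


def expected_class_records() -> list[dict]:
    return [
        {"strain": s, "marker": m, "stage": st, "expected_class": c,
         "provenance": prov}
        for s, m, st, c, prov in EXPECTED_CLASSES
    ]


def planted_motif_fasta(seed: int = 0, length: int = 5_000,
                        plants: dict[int, str] | None = None
                        ) -> tuple[str, dict[int, str]]:
    """A random sequence with motif sites planted at known positions.

    Returns (sequence, {position: site}).  Default plants: tidR exact at 101
    and a one-mismatch consensus variant (GATGACGTCAGC) at 501.  The random
    background is rejected-sampled so that no *unplanned* window comes within
    2 mismatches of the consensus.
    """
    from .motifs import TID_CONSENSUS, mismatch_count, reverse_complement

    if plants is None:
        plants = {101: TIDR_SEQ, 501: "GATGACGTCAGC"}
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(rng.choice(bases, size=length))
        clean = True
        for i in range(length - 11):
            w = seq[i:i + 12]
            if (mismatch_count(w, TID_CONSENSUS) <= 2
                    or mismatch_count(reverse_complement(w), TID_CONSENSUS) <= 2):
                clean = False
                break
        if clean:
            break
    arr = list(seq)
    for pos, site in plants.items():
        arr[pos - 1:pos - 1 + len(site)] = list(site)
    return "".join(arr), dict(plants)
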