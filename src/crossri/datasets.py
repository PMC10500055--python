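"""Published summary tables of the parasitoid-wasp crossing study.

These small datasets ship with the package (statsmodels-style) so the
worked examples and the reproduction script can run without downloads:

* the replicate counts of the cytoplasmic-incompatibility crossing
  experiment between the uninfected BIR strain and the
  endosymbiont-infected STU strain (crosses with / without female
  offspring per combination),
* the per-barrier reproductive-isolation indices of all ten crossing
  directions, with the published totals,
* the COI barcode divergences between the strain pairs.

``NOT_STUDIED`` marks barriers the study could not assess for a pair
(they are skipped in the cascade, not imputed).
"""

from __future__ import annotations

import math

from crossri.crossdata import CrossRecord, CrossSet, cross_label
from crossri.ri import Barrier

NOT_STUDIED = None

#: replicate counts of the CI experiment:
#: combination -> (crosses with female offspring, total crosses)
CI_CROSS_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("BIR", "BIR"): (21, 21),
    ("BIR", "STU_tet"): (39, 39),
    ("BIR", "STU"): (19, 40),
    ("STU", "BIR"): (33, 38),
    ("STU", "STU"): (29, 33),
}


def ci_crossing_table() -> CrossSet:
    """The CI experiment as replicate-level records.

    Each cross is encoded with its occurrence outcome (>=1 female
    offspring or none); per-cross brood sizes were not published, so
    nominal single-offspring counts are used — sufficient for every
    occurrence-based statistic.
    """
    records = []
    for (f, m), (with_f, n) in CI_CROSS_COUNTS.items():
        for i in range(n):
            has_female = i < with_f
            records.append(CrossRecord(
                cross_id=f"{f}x{m}_{i + 1:02d}",
                female_strain=f, male_strain=m,
                female_origin="parental", generation="P",
                treatment="untreated",
                mating_observed="not_observed",
                virgin_female=False,
                n_offspring_total=2 if has_female else 1,
                n_offspring_female=1 if has_female else 0,
                n_offspring_male=1,
            ))
    return CrossSet(records, metadata={"study": "CI crossing experiment",
                                       "schema_version": "1"})


_DIRECTIONS = (
    ("BIR", "OST"), ("OST", "BIR"),
    ("BIR", "STU"), ("STU", "BIR"),
    ("CAN", "STU"), ("STU", "CAN"),
    ("BIR", "SAT"), ("SAT", "BIR"),
    ("CAN", "PFO"), ("PFO", "CAN"),
)

_RI_ROWS: dict[Barrier, tuple] = {
    Barrier.SEXUAL:
        (-0.44, 0.27, -0.08, 0.14, -0.08, 0.53, 1.0, 0.62, 1.0, 0.71),
    Barrier.FEMALE_INVIABILITY:
        (0.03, -0.05, -0.03, 0.13, 0.13, 0.06, 0.37, -0.13, 0.95, 0.04),
    Barrier.FEMALE_BEHAV_STERILITY:
        (-0.19, 0.08, -0.02, -0.03, 0.47, 0.67,
         NOT_STUDIED, NOT_STUDIED, NOT_STUDIED, NOT_STUDIED),
    Barrier.FEMALE_PHYS_STERILITY:
        (0.02, 0.04, 0.0, 0.01, 0.03, 0.0, 0.0, -0.11, NOT_STUDIED, -0.03),
    Barrier.FEMALE_REDUCED_FERTILITY:
        (-0.02, -0.08, -0.14, -0.06, 0.14, -0.05, 0.0, 0.06,
         NOT_STUDIED, 0.51),
    Barrier.MALE_INVIABILITY:
        (-0.07, -0.08, 0.0, 0.05, -0.09, -0.02, 0.58, 0.86,
         NOT_STUDIED, 0.76),
    Barrier.MALE_BEHAV_STERILITY:
        (0.05, -0.03, 0.01, 0.01, 0.21, 0.15, 0.51, 0.68, NOT_STUDIED, 0.51),
    Barrier.MALE_PHYS_STERILITY:
        (0.0, 0.01, -0.01, -0.01, -0.02, 0.06, 0.29, 0.20, NOT_STUDIED, 0.35),
    Barrier.MALE_REDUCED_FERTILITY:
        (0.09, 0.13, -0.01, -0.1, 0.34, 0.40, 0.37, 0.23, NOT_STUDIED, 0.40),
}

#: hybrid-female inviability with cytoplasmic incompatibility expressed
#: (only assessed for the BIR x STU pair)
RI_WITH_CI: dict[tuple[str, str], float] = {
    ("BIR", "STU"): 0.356,
    ("STU", "BIR"): 0.006,
}

#: published totals of the sequential cascade (computed by the study
#: authors from unrounded per-barrier values)
TOTAL_ISOLATION: dict[tuple[str, str], dict[str, float]] = {
    ("BIR", "OST"): {"without_CI": -0.5276},
    ("OST", "BIR"): {"without_CI": 0.2949},
    ("BIR", "STU"): {"without_CI": -0.2785, "with_CI": 0.0860},
    ("STU", "BIR"): {"without_CI": 0.1436, "with_CI": 0.1498},
    ("CAN", "STU"): {"without_CI": 0.8319},
    ("STU", "CAN"): {"without_CI": 0.9651},
    ("BIR", "SAT"): {"without_CI": 1.0},
    ("SAT", "BIR"): {"without_CI": 0.996},
    ("CAN", "PFO"): {"without_CI": 1.0},
    ("PFO", "CAN"): {"without_CI": 0.9991},
}

#: COI barcode divergence between the crossed strain pairs (proportion)
COI_DIFFERENCE: dict[tuple[str, str], float] = {
    ("BIR", "OST"): 0.017,
    ("BIR", "STU"): 0.028,
    ("CAN", "STU"): 0.072,
    ("BIR", "SAT"): 0.139,
    ("CAN", "PFO"): 0.140,
}

#: mean COI p-distance between barcode clades (clade A/B within the
#: drugstore-beetle species group, clade C the granary-weevil group)
CLADE_MEAN_DISTANCE: dict[tuple[str, str], float] = {
    ("A", "B"): 0.0717,
    ("A", "C"): 0.1328,
    ("B", "C"): 0.1422,
}


def published_barrier_ri(direction: tuple[str, str],
                         ci_variant: str = "without_CI") -> list[float | None]:
    """Per-barrier RI values of one direction, in cascade order.

    ``None`` marks a barrier not studied for that direction. With
    ``ci_variant="with_CI"`` the hybrid-female-inviability entry is the
    occurrence-based index under expressed CI (only available for the
    BIR x STU pair).
    """
    direction = tuple(direction)
    if direction not in _DIRECTIONS:
        raise KeyError(
            f"unknown direction {cross_label(*direction)}; known: "
            f"{[cross_label(*d) for d in _DIRECTIONS]}")
    col = _DIRECTIONS.index(direction)
    values: list[float | None] = []
    for barrier, row in _RI_ROWS.items():
        v = row[col]
        if (ci_variant == "with_CI"
                and barrier is Barrier.FEMALE_INVIABILITY):
            v = RI_WITH_CI.get(direction)
            if v is None:
                raise KeyError(
                    f"no with-CI inviability index for "
                    f"{cross_label(*direction)}")
        values.append(v)
    return values


def published_total_isolation(direction: tuple[str, str],
                              ci_variant: str = "without_CI") -> float:
    t = TOTAL_ISOLATION[tuple(direction)].get(ci_variant)
    return math.nan if t is None else t


def crossing_directions() -> list[tuple[str, str]]:
    return list(_DIRECTIONS)
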