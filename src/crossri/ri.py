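"""Reproductive-isolation indices and the sequential barrier cascade.

A barrier's strength is measured by the unified index

    RI = 1 - 2H/(H + C)

where ``H`` is an outcome measured on interstrain (hybrid) crosses and
``C`` the same outcome on the matching intrastrain control. RI is 0
under random gene flow, 1 at complete isolation and negative when the
interstrain outcome exceeds the control (outcrossing favoured).

Barriers act in sequence: a barrier can only block gene flow that
earlier barriers let through. Its absolute contribution at position
``n`` is

    AC_n = RI_n * (1 - sum_{i<n} AC_i)

and total isolation is ``T = sum_i AC_i``, which equals
``1 - prod_i (1 - RI_i)`` algebraically.

:func:`build_barrier_ladder` maps a validated
:class:`~crossri.crossdata.CrossSet` to the ladder of barrier estimates
for one strain-pair direction. The outcome metric per barrier follows
the study design:

==================================  =======================================
barrier                             metric (H and C alike)
==================================  =======================================
sexual_isolation_parental           proportion of parental pairs copulating
hybrid_female_inviability
  (CI-free variant)                 mean F1 female count, female-bearing
                                    crosses only
  (with-CI variant)                 proportion of crosses with >=1 female
                                    offspring (untreated wasps)
hybrid_female_behavioural_steril.   proportion of F1 females copulating
hybrid_female_physiological_ster.   proportion of F1-female crosses with
                                    any F2 offspring
hybrid_female_reduced_fertility     mean total F2 offspring, offspring-
                                    bearing crosses only
hybrid_male_inviability             mean male offspring of virgin F1
                                    females, offspring-bearing only
hybrid_male_behavioural_sterility   backcross copulation proportion
hybrid_male_physiological_steril.   proportion of backcrosses with female
                                    offspring
hybrid_male_reduced_fertility       mean female offspring of backcrosses,
                                    female-bearing only
==================================  =======================================

Hybrid-male barriers from behavioural sterility onward are estimated
separately against parental-type females of both strains and the two RI
values averaged before entering the cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from crossri.crossdata import CrossSet, cross_label


class Barrier(str, Enum):
    """Ladder stages in cascade order."""

    ECOLOGICAL = "ecological_isolation"  # qualitative annotation only
    SEXUAL = "sexual_isolation_parental"
    FEMALE_INVIABILITY = "hybrid_female_inviability"
    FEMALE_BEHAV_STERILITY = "hybrid_female_behavioural_sterility"
    FEMALE_PHYS_STERILITY = "hybrid_female_physiological_sterility"
    FEMALE_REDUCED_FERTILITY = "hybrid_female_reduced_fertility"
    MALE_INVIABILITY = "hybrid_male_inviability"
    MALE_BEHAV_STERILITY = "hybrid_male_behavioural_sterility"
    MALE_PHYS_STERILITY = "hybrid_male_physiological_sterility"
    MALE_REDUCED_FERTILITY = "hybrid_male_reduced_fertility"


#: numeric cascade order (ecological isolation never enters the cascade)
CASCADE_ORDER: tuple[Barrier, ...] = (
    Barrier.SEXUAL,
    Barrier.FEMALE_INVIABILITY,
    Barrier.FEMALE_BEHAV_STERILITY,
    Barrier.FEMALE_PHYS_STERILITY,
    Barrier.FEMALE_REDUCED_FERTILITY,
    Barrier.MALE_INVIABILITY,
    Barrier.MALE_BEHAV_STERILITY,
    Barrier.MALE_PHYS_STERILITY,
    Barrier.MALE_REDUCED_FERTILITY,
)

#: barriers averaged over backcrosses to both parental-type female strains
AVERAGED_BARRIERS = (
    Barrier.MALE_BEHAV_STERILITY,
    Barrier.MALE_PHYS_STERILITY,
    Barrier.MALE_REDUCED_FERTILITY,
)

CI_VARIANTS = ("with_CI", "without_CI", "not_applicable")


# ---------------------------------------------------------------------------
# core arithmetic

def ri_index(H: float, C: float) -> float:
    """Unified reproductive-isolation index ``1 - 2H/(H+C)``.

    Both arguments must be non-negative measures on the same scale
    (proportions or mean counts). Returns NaN when ``H + C == 0``
    (barrier unmeasurable; skipped downstream).
    """
    if H < 0 or C < 0:
        raise ValueError(f"H and C must be non-negative (H={H}, C={C})")
    if H + C == 0:
        return math.nan
    return 1.0 - 2.0 * H / (H + C)


def absolute_contributions(ri_sequence: Sequence[float]) -> list[float]:
    """Sequential absolute contribution of each barrier.

    ``AC_1 = RI_1`` and ``AC_n = RI_n * (1 - sum_{i<n} AC_i)``: each
    barrier only removes the gene flow remaining after earlier ones.
    """
    acs: list[float] = []
    cum = 0.0
    for ri in ri_sequence:
        ac = ri * (1.0 - cum)
        acs.append(ac)
        cum += ac
    return acs


def total_isolation(ri_sequence: Sequence[float]) -> float:
    """Total isolation ``T = sum AC_i`` (equals ``1 - prod(1 - RI_i)``).

    NaN for an empty sequence (no measurable barrier).
    """
    seq = list(ri_sequence)
    if not seq:
        return math.nan
    return sum(absolute_contributions(seq))


# ---------------------------------------------------------------------------
# estimates and ladders

@dataclass(frozen=True)
class BarrierEstimate:
    """One barrier's H, C and RI for one strain-pair direction."""

    barrier: Barrier
    direction: tuple[str, str]
    H: float
    C: float
    RI: float
    metric: str  # "proportion" or "mean_count"
    n_H: int
    n_C: int
    significant: bool | None = None  # None = not tested
    p_value: float | None = None
    test_name: str | None = None
    #: per-parental-female-strain components for averaged male barriers
    components: tuple["BarrierEstimate", ...] = ()

    def __post_init__(self) -> None:
        if not math.isnan(self.RI) and self.H + self.C > 0:
            expect = ri_index(self.H, self.C)
            if abs(self.RI - expect) > 1e-9 and not self.components:
                raise ValueError(
                    f"{self.barrier.value}: RI={self.RI} inconsistent with "
                    f"H={self.H}, C={self.C} (expected {expect})")


@dataclass
class BarrierLadder:
    """Ordered barrier estimates with cascade contributions and total."""

    direction: tuple[str, str]
    estimates: list[BarrierEstimate]
    ci_variant: str = "not_applicable"
    ecological: str | None = None  # qualitative annotation, never numeric
    skipped: list[Barrier] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ci_variant not in CI_VARIANTS:
            raise ValueError(f"unknown ci_variant {self.ci_variant!r}")

    @property
    def ri_values(self) -> list[float]:
        return [e.RI for e in self.estimates]

    @property
    def AC(self) -> list[float]:
        return absolute_contributions(self.ri_values)

    @property
    def T(self) -> float:
        return total_isolation(self.ri_values)

    def to_frame(self) -> pd.DataFrame:
        """Ladder as a tidy table (one row per barrier, plus the total)."""
        rows = []
        acs = self.AC
        for e, ac in zip(self.estimates, acs):
            rows.append({
                "barrier": e.barrier.value,
                "metric": e.metric,
                "H": e.H, "C": e.C,
                "n_H": e.n_H, "n_C": e.n_C,
                "RI": e.RI, "AC": ac,
                "significant": e.significant,
                "p_value": e.p_value,
                "test": e.test_name,
            })
        frame = pd.DataFrame(rows)
        frame.attrs["direction"] = cross_label(*self.direction)
        frame.attrs["total_isolation"] = self.T
        frame.attrs["ci_variant"] = self.ci_variant
        return frame


def ladder_from_ri_values(
    ri_values: Iterable[float | None],
    direction: tuple[str, str] = ("A", "B"),
    barriers: Sequence[Barrier] | None = None,
    ci_variant: str = "not_applicable",
) -> BarrierLadder:
    """Build a ladder from precomputed per-barrier RI values.

    ``None``/NaN entries mark barriers that were not studied; they are
    skipped and later positions renumber. Used to re-cascade published
    per-barrier indices.
    """
    values = list(ri_values)
    names = list(barriers) if barriers is not None else list(CASCADE_ORDER)[:len(values)]
    if len(names) < len(values):
        raise ValueError("more RI values than barrier names")
    estimates, skipped = [], []
    for name, v in zip(names, values):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            skipped.append(name)
            continue
        # H/C placeholders consistent with the index: RI = 1-2H/(H+C)
        # with H = (1-RI)/2, C = (1+RI)/2.
        estimates.append(BarrierEstimate(
            barrier=name, direction=direction,
            H=(1.0 - v) / 2.0, C=(1.0 + v) / 2.0, RI=float(v),
            metric="proportion", n_H=0, n_C=0))
    return BarrierLadder(direction=direction, estimates=estimates,
                         ci_variant=ci_variant, skipped=skipped)


# ---------------------------------------------------------------------------
# ladder construction from cross records

@dataclass
class LadderConfig:
    """Configuration of :func:`build_barrier_ladder`.

    ci_variant
        ``with_CI`` computes hybrid-female inviability as the occurrence
        of female offspring on untreated wasps (cytoplasmic
        incompatibility expressed); ``without_CI`` uses the mean female
        count on endosymbiont-free (tetracycline-treated where
        available) wasps; ``not_applicable`` for pairs without a CI
        assay (same metric as ``without_CI``).
    run_tests
        attach a significance verdict per barrier (contingency test for
        proportions, permutation test for counts).
    """

    ci_variant: str = "not_applicable"
    barriers: tuple[Barrier, ...] = CASCADE_ORDER
    run_tests: bool = False
    alpha: float = 0.05
    test_seed: int = 0
    n_perm: int = 10_000
    ecological: str | None = None

    def __post_init__(self) -> None:
        if self.ci_variant not in CI_VARIANTS:
            raise ValueError(f"unknown ci_variant {self.ci_variant!r}")


def available_directions(cs: CrossSet) -> list[tuple[str, str]]:
    """Ordered strain pairs with parental interstrain crosses in ``cs``."""
    f = cs.to_frame()
    p = f[(f["generation"] == "P")
          & (f["female_strain"] != f["male_strain"])]
    return sorted(set(zip(p["female_strain"], p["male_strain"])))


def build_barrier_ladder(
    cs: CrossSet,
    direction: tuple[str, str],
    config: LadderConfig | None = None,
) -> BarrierLadder:
    """Estimate the full barrier ladder for one strain-pair direction.

    Controls are always intrastrain crosses with females of the same
    strain as the interstrain cross (or, for hybrid-line tests, the
    matching non-hybrid line). Barriers without data are skipped, not
    imputed. Raises ``KeyError`` listing available directions when the
    requested one is absent.
    """
    config = config or LadderConfig()
    female, male = direction
    frame = cs.to_frame()
    if direction not in available_directions(cs):
        raise KeyError(
            f"direction {cross_label(female, male)} not in data; "
            f"available: "
            f"{[cross_label(*d) for d in available_directions(cs)]}")

    builder = _LadderBuilder(frame, direction, config)
    estimates, skipped = [], []
    for barrier in config.barriers:
        if barrier is Barrier.ECOLOGICAL:
            continue
        est = builder.estimate(barrier)
        if est is None or math.isnan(est.RI):
            skipped.append(barrier)
        else:
            estimates.append(est)
    return BarrierLadder(direction=direction, estimates=estimates,
                         ci_variant=config.ci_variant,
                         ecological=config.ecological, skipped=skipped)


class _LadderBuilder:
    def __init__(self, frame: pd.DataFrame, direction: tuple[str, str],
                 config: LadderConfig):
        self.f = frame
        self.female, self.male = direction
        self.direction = direction
        self.config = config
        self.label_inter = cross_label(self.female, self.male)

    # -- group selection ----------------------------------------------------
    def _prefer_treated(self, g: pd.DataFrame) -> pd.DataFrame:
        """CI-free measurement: tetracycline-treated records where present."""
        treated = g[g["treatment"] == "tetracycline"]
        return treated if len(treated) else g[g["treatment"] == "untreated"]

    def _parental(self, fs: str, ms: str, treatment: str = "prefer_treated"
                  ) -> pd.DataFrame:
        g = self.f[(self.f["generation"] == "P")
                   & (self.f["female_origin"] == "parental")
                   & (self.f["female_strain"] == fs)
                   & (self.f["male_strain"] == ms)
                   & (~self.f["virgin_female"])]
        if treatment == "untreated":
            return g[g["treatment"] == "untreated"]
        return self._prefer_treated(g)

    def _f1_test(self, origin: str, virgin: bool) -> pd.DataFrame:
        g = self.f[(self.f["generation"] == "F1_female_test")
                   & (self.f["female_origin"] == origin)
                   & (self.f["virgin_female"] == virgin)]
        return self._prefer_treated(g)

    def _backcross(self, female_strain: str, origin: str) -> pd.DataFrame:
        g = self.f[(self.f["generation"] == "F2_male_backcross")
                   & (self.f["female_strain"] == female_strain)
                   & (self.f["female_origin"] == origin)]
        return self._prefer_treated(g)

    # -- metrics ------------------------------------------------------------
    @staticmethod
    def _copulation(g: pd.DataFrame) -> tuple[float, int, int]:
        assessed = g[g["mating_observed"] != "not_observed"]
        n = len(assessed)
        if n == 0:
            return math.nan, 0, 0
        k = int((assessed["mating_observed"] == "yes").sum())
        return k / n, n, k

    @staticmethod
    def _occurrence(g: pd.DataFrame, column: str) -> tuple[float, int, int]:
        n = len(g)
        if n == 0:
            return math.nan, 0, 0
        k = int((g[column] >= 1).sum())
        return k / n, n, k

    @staticmethod
    def _bearing_mean(g: pd.DataFrame, column: str) -> tuple[float, int, np.ndarray]:
        bearing = g[g[column] >= 1]
        if len(bearing) == 0:
            return math.nan, 0, np.empty(0, dtype=int)
        vals = bearing[column].to_numpy()
        return float(vals.mean()), len(bearing), vals

    # -- barrier estimates --------------------------------------------------
    def estimate(self, barrier: Barrier) -> BarrierEstimate | None:
        if barrier in AVERAGED_BARRIERS:
            return self._averaged_male_barrier(barrier)
        spec = self._single_groups(barrier)
        if spec is None:
            return None
        gH, gC, kind, column = spec
        return self._two_group_estimate(barrier, gH, gC, kind, column)

    def _single_groups(self, barrier: Barrier):
        F, M = self.female, self.male
        if barrier is Barrier.SEXUAL:
            return (self._parental(F, M), self._parental(F, F),
                    "copulation", None)
        if barrier is Barrier.FEMALE_INVIABILITY:
            if self.config.ci_variant == "with_CI":
                return (self._parental(F, M, treatment="untreated"),
                        self._parental(F, F, treatment="untreated"),
                        "occurrence", "n_offspring_female")
            return (self._parental(F, M), self._parental(F, F),
                    "bearing_mean", "n_offspring_female")
        o_inter, o_intra = self.label_inter, cross_label(F, F)
        if barrier is Barrier.FEMALE_BEHAV_STERILITY:
            return (self._f1_test(o_inter, False), self._f1_test(o_intra, False),
                    "copulation", None)
        if barrier is Barrier.FEMALE_PHYS_STERILITY:
            return (self._f1_test(o_inter, False), self._f1_test(o_intra, False),
                    "occurrence", "n_offspring_total")
        if barrier is Barrier.FEMALE_REDUCED_FERTILITY:
            return (self._f1_test(o_inter, False), self._f1_test(o_intra, False),
                    "bearing_mean", "n_offspring_total")
        if barrier is Barrier.MALE_INVIABILITY:
            return (self._f1_test(o_inter, True), self._f1_test(o_intra, True),
                    "bearing_mean", "n_offspring_male")
        raise AssertionError(barrier)

    def _two_group_estimate(self, barrier, gH, gC, kind, column,
                            direction=None) -> BarrierEstimate | None:
        if kind == "copulation":
            H, n_H, k_H = self._copulation(gH)
            C, n_C, k_C = self._copulation(gC)
            metric = "proportion"
            test_data = ("binary", k_H, n_H, k_C, n_C)
        elif kind == "occurrence":
            H, n_H, k_H = self._occurrence(gH, column)
            C, n_C, k_C = self._occurrence(gC, column)
            metric = "proportion"
            test_data = ("binary", k_H, n_H, k_C, n_C)
        else:  # bearing_mean
            H, n_H, vals_H = self._bearing_mean(gH, column)
            C, n_C, vals_C = self._bearing_mean(gC, column)
            metric = "mean_count"
            test_data = ("count", vals_H, vals_C)
        if n_H == 0 or n_C == 0:
            return None
        if math.isnan(H) or math.isnan(C):
            return None
        RI = ri_index(H, C)
        est = BarrierEstimate(
            barrier=barrier, direction=direction or self.direction,
            H=H, C=C, RI=RI, metric=metric, n_H=n_H, n_C=n_C)
        if self.config.run_tests:
            est = self._attach_test(est, test_data)
        return est

    def _averaged_male_barrier(self, barrier: Barrier) -> BarrierEstimate | None:
        kind, column = {
            Barrier.MALE_BEHAV_STERILITY: ("copulation", None),
            Barrier.MALE_PHYS_STERILITY: ("occurrence", "n_offspring_female"),
            Barrier.MALE_REDUCED_FERTILITY: ("bearing_mean", "n_offspring_female"),
        }[barrier]
        components = []
        for strain in (self.female, self.male):
            gH = self._backcross(strain, self.label_inter)
            gC = self._backcross(strain, cross_label(strain, strain))
            est = self._two_group_estimate(
                barrier, gH, gC, kind, column,
                direction=(strain, self.label_inter))
            if est is not None:
                components.append(est)
        if not components:
            return None
        mean_ri = float(np.mean([c.RI for c in components]))
        any_sig = (any(bool(c.significant) for c in components)
                   if self.config.run_tests else None)
        ref = components[0]
        return BarrierEstimate(
            barrier=barrier, direction=self.direction,
            H=float(np.mean([c.H for c in components])),
            C=float(np.mean([c.C for c in components])),
            RI=mean_ri, metric=ref.metric,
            n_H=sum(c.n_H for c in components),
            n_C=sum(c.n_C for c in components),
            significant=any_sig,
            components=tuple(components))

    def _attach_test(self, est: BarrierEstimate, test_data) -> BarrierEstimate:
        from crossri import stats as bstats
        if test_data[0] == "binary":
            _, k_H, n_H, k_C, n_C = test_data
            table = np.array([[k_H, n_H - k_H], [k_C, n_C - k_C]])
            if table.sum() == 0:
                return est
            result = bstats.run_binary_comparison(
                table, alpha=self.config.alpha, seed=self.config.test_seed)
        else:
            _, vals_H, vals_C = test_data
            if len(vals_H) < 2 or len(vals_C) < 2:
                return est
            result = bstats.permutation_two_group(
                vals_H, vals_C, n_perm=self.config.n_perm,
                seed=self.config.test_seed, alpha=self.config.alpha)
        return replace(est, significant=result.p_value < self.config.alpha,
                       p_value=result.p_value, test_name=result.test_name)


# ---------------------------------------------------------------------------
# export

def ladders_to_table(ladders: Sequence[BarrierLadder]) -> pd.DataFrame:
    """Wide report: rows = barriers + total, columns = directions."""
    cols = {}
    for lad in ladders:
        label = cross_label(*lad.direction)
        if lad.ci_variant != "not_applicable":
            label += f" [{lad.ci_variant}]"
        col = {}
        for e in lad.estimates:
            star = "*" if e.significant else ""
            col[e.barrier.value] = f"{e.RI:.4g}{star}"
        for b in lad.skipped:
            col[b.value] = "not_studied"
        col["total_isolation"] = f"{lad.T:.4g}"
        cols[label] = col
    order = [b.value for b in CASCADE_ORDER] + ["total_isolation"]
    return pd.DataFrame(cols).reindex(order)
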