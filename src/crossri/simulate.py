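"""Synthetic crossing-experiment and barcode-alignment generator.

The generator emulates the study design end to end with known
ground-truth barrier strengths, so every pipeline stage can be tested
without the deposited raw data:

* per-pair binary copulation outcomes (Bernoulli),
* haplodiploid offspring sex allocation — mated females produce mixed
  broods, virgin or unmated females produce sons only (arrhenotoky),
* overdispersed brood sizes (negative binomial; Poisson as the
  infinite-dispersion limit),
* unidirectional endosymbiont-induced cytoplasmic incompatibility:
  crosses of an uninfected female with an infected, untreated male lose
  their female offspring with penetrance ``c`` (all-or-nothing per
  cross by default; a binomial thinning variant is available),
* hybrid effects as multiplicative factors on mating probability,
  brood size, or daughter production for the F1-female and F2-male
  test stages.

:func:`true_ri` returns the model-implied expected RI for each barrier
in closed form (using the negative-binomial zero mass
``P0 = (k/(k+mu))^k`` for occurrence metrics and the zero-truncated
mean ``mu/(1-P0)`` for conditional means), serving as the recovery
target for the estimation pipeline.

Randomness: one global seed; every replicate group draws from its own
substream keyed by a CRC of the group label, so adding a combination
never perturbs existing ones.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from crossri.crossdata import COLUMNS, CrossSet, cross_label
from crossri.distances import Alignment
from crossri.ri import Barrier, ri_index


@dataclass
class StrainSpec:
    """Intrastrain baselines of one strain.

    p_mate: copulation probability of a within-strain pair.
    mu, k:  negative-binomial brood size (mean, dispersion; ``k=inf``
            gives Poisson).
    s_f:    probability an offspring of a mated female is a daughter.
    infected: carries the CI-inducing endosymbiont.
    """

    infected: bool = False
    clade: str = ""
    p_mate: float = 0.75
    mu: float = 30.0
    k: float = 5.0
    s_f: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mate <= 1.0:
            raise ValueError(f"p_mate out of [0,1]: {self.p_mate}")
        if not 0.0 <= self.s_f <= 1.0:
            raise ValueError(f"s_f out of [0,1]: {self.s_f}")
        if self.mu <= 0 or self.k <= 0:
            raise ValueError("mu and k must be positive")


@dataclass
class DirectionParams:
    """Interstrain parameters of one ordered pair (female, male).

    All hybrid effects are multiplicative factors in [0, 1+] relative
    to the female strain's baseline; 1.0 means no barrier.
    """

    p_mate: float | None = None  # None: female strain baseline
    female_viability: float = 1.0   # survival of hybrid daughters
    female_behaviour: float = 1.0   # mating propensity of hybrid F1 females
    female_fertility: float = 1.0   # brood size of hybrid F1 females
    male_viability: float = 1.0     # brood size of virgin hybrid F1 females
    male_behaviour: float = 1.0     # backcross mating success of hybrid males
    male_fertility: float = 1.0     # daughter production of hybrid males


@dataclass
class SimulationConfig:
    """Ground truth for one simulated crossing experiment."""

    strains: dict[str, StrainSpec]
    directions: list[tuple[str, str]]
    params: dict[tuple[str, str], DirectionParams] = field(default_factory=dict)
    n_rep: int = 40
    ci_penetrance: float = 0.525
    ci_mode: str = "all_or_nothing"  # or "thinning"
    simulate_treated: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_penetrance <= 1.0:
            raise ValueError("ci_penetrance out of [0,1]")
        if self.ci_mode not in ("all_or_nothing", "thinning"):
            raise ValueError(f"unknown ci_mode {self.ci_mode!r}")
        self.directions = [tuple(d) for d in self.directions]
        for f, m in self.directions:
            for s in (f, m):
                if s not in self.strains:
                    raise ValueError(f"direction references unknown strain {s!r}")
        self.params = {tuple(k): v for k, v in self.params.items()}
        for d in self.directions:
            self.params.setdefault(d, DirectionParams())

    def direction_params(self, direction: tuple[str, str]) -> DirectionParams:
        return self.params.get(tuple(direction), DirectionParams())

    def inter_p_mate(self, direction: tuple[str, str]) -> float:
        dp = self.direction_params(direction)
        return (dp.p_mate if dp.p_mate is not None
                else self.strains[direction[0]].p_mate)

    def ci_applies(self, female: str, male: str, treated: bool) -> bool:
        """CI hits crosses of uninfected females with infected males."""
        return (not treated
                and not self.strains[female].infected
                and self.strains[male].infected)

    def to_dict(self) -> dict:
        return {
            "strains": {k: asdict(v) for k, v in self.strains.items()},
            "directions": [list(d) for d in self.directions],
            "params": {cross_label(*k): asdict(v)
                       for k, v in self.params.items()},
            "n_rep": self.n_rep,
            "ci_penetrance": self.ci_penetrance,
            "ci_mode": self.ci_mode,
            "simulate_treated": self.simulate_treated,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        strains = {k: StrainSpec(**v) for k, v in data["strains"].items()}
        params = {}
        for label, v in data.get("params", {}).items():
            f, m = label.rstrip("♂").split("♀×")
            params[(f, m)] = DirectionParams(**v)
        return cls(
            strains=strains,
            directions=[tuple(d) for d in data["directions"]],
            params=params,
            n_rep=int(data.get("n_rep", 40)),
            ci_penetrance=float(data.get("ci_penetrance", 0.525)),
            ci_mode=data.get("ci_mode", "all_or_nothing"),
            simulate_treated=bool(data.get("simulate_treated", True)),
            seed=int(data.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# helpers

def _substream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _draw_counts(rng: np.random.Generator, mu: float, k: float,
                 size: int) -> np.ndarray:
    if mu <= 0:
        return np.zeros(size, dtype=np.int64)
    if math.isinf(k):
        return rng.poisson(mu, size)
    return rng.negative_binomial(k, k / (k + mu), size)


def _p_zero(mu: float, k: float) -> float:
    if mu <= 0:
        return 1.0
    if math.isinf(k):
        return math.exp(-mu)
    return (k / (k + mu)) ** k


def _cond_mean(mu: float, k: float) -> float:
    """Mean of the zero-truncated brood-size distribution."""
    p0 = _p_zero(mu, k)
    if p0 >= 1.0:
        return math.nan
    return mu / (1.0 - p0)


# ---------------------------------------------------------------------------
# cross-series simulation

def simulate_cross_series(cfg: SimulationConfig,
                          seed: int | None = None) -> CrossSet:
    """Simulate the full multi-generation crossing series.

    For every requested direction the output contains the parental
    inter- and intrastrain crosses, F1-female mating/oviposition and
    virgin-oviposition tests for hybrid and control lines, and
    F2-male backcrosses to both parental-type female strains — the
    complete input for :func:`crossri.ri.build_barrier_ladder`. When a
    direction is CI-relevant and ``simulate_treated`` is set,
    tetracycline-treated replicate groups are generated alongside so
    the CI-free ladder variant can be estimated.
    """
    seed = cfg.seed if seed is None else seed
    rows: list[tuple] = []
    done: set[tuple] = set()

    def emit(kind, *args, **kw):
        key = (kind,) + args
        if key in done:
            return
        done.add(key)
        rows.extend(kw["make"](key))

    for direction in cfg.directions:
        F, M = direction
        treatments = ["untreated"]
        ci_pair = cfg.ci_applies(F, M, treated=False) or \
            cfg.ci_applies(M, F, treated=False)
        if ci_pair and cfg.simulate_treated:
            treatments.append("tetracycline")
        for treated in treatments:
            is_t = treated == "tetracycline"
            # parental crosses: inter + both intrastrain controls
            for fs, ms in ((F, M), (F, F), (M, M)):
                emit("P", fs, ms, treated,
                     make=lambda key, fs=fs, ms=ms, t=treated:
                     _parental_group(cfg, seed, fs, ms, t,
                                     direction if (fs, ms) == (F, M) else None))
            # F1-female tests: hybrid line and female-strain control line
            for origin_pair in ((F, M), (F, F)):
                hybrid = origin_pair[0] != origin_pair[1]
                for virgin in (False, True):
                    emit("F1", origin_pair, virgin, treated,
                         make=lambda key, op=origin_pair, v=virgin, t=treated,
                         h=hybrid:
                         _f1_group(cfg, seed, op, v, t, direction if h else None))
            # F2-male backcrosses to each parental-type female strain
            for S in (F, M):
                for origin_pair in ((F, M), (S, S)):
                    hybrid = origin_pair[0] != origin_pair[1]
                    emit("F2", S, origin_pair, treated,
                         make=lambda key, s=S, op=origin_pair, t=treated,
                         h=hybrid:
                         _backcross_group(cfg, seed, s, op, t,
                                          direction if h else None))
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame["cross_id"] = [f"sim{i:05d}" for i in range(len(frame))]
    return CrossSet(frame, metadata={"generator": "crossri.simulate",
                                     "seed": seed}, validate=False)


def _parental_group(cfg, seed, fs, ms, treatment, direction):
    spec_f = cfg.strains[fs]
    inter = direction is not None
    dp = cfg.direction_params(direction) if inter else DirectionParams()
    p = cfg.inter_p_mate(direction) if inter else spec_f.p_mate
    label = f"P|{cross_label(fs, ms)}|{treatment}"
    rng = _substream(seed, label)
    n = cfg.n_rep
    mated = rng.random(n) < p
    total = _draw_counts(rng, spec_f.mu, spec_f.k, n)
    s_daughter = spec_f.s_f * (dp.female_viability if inter else 1.0)
    females = np.where(mated, rng.binomial(total, min(s_daughter, 1.0)), 0)
    if cfg.ci_applies(fs, ms, treated=treatment == "tetracycline"):
        if cfg.ci_mode == "all_or_nothing":
            hit = rng.random(n) < cfg.ci_penetrance
            females = np.where(hit, 0, females)
        else:
            females = rng.binomial(females, 1.0 - cfg.ci_penetrance)
    males = total - females  # sons: unfertilised eggs + inviable daughters
    return _rows(fs, ms, "parental", "P", treatment,
                 np.where(mated, "yes", "no"), False, total, females, males)


def _f1_group(cfg, seed, origin_pair, virgin, treatment, direction):
    of, om = origin_pair
    spec = cfg.strains[of]
    hybrid = direction is not None
    dp = cfg.direction_params(direction) if hybrid else DirectionParams()
    origin = cross_label(of, om)
    kind = "virgin" if virgin else "mated"
    rng = _substream(seed, f"F1|{origin}|{kind}|{treatment}")
    n = cfg.n_rep
    if virgin:
        mu = spec.mu * (dp.male_viability if hybrid else 1.0)
        total = _draw_counts(rng, mu, spec.k, n)
        return _rows(of, om, origin, "F1_female_test", treatment,
                     np.repeat("not_observed", n), True,
                     total, np.zeros(n, dtype=np.int64), total)
    p = spec.p_mate * (dp.female_behaviour if hybrid else 1.0)
    mated = rng.random(n) < min(p, 1.0)
    mu = spec.mu * (dp.female_fertility if hybrid else 1.0)
    total = _draw_counts(rng, mu, spec.k, n)
    females = np.where(mated, rng.binomial(total, spec.s_f), 0)
    return _rows(of, om, origin, "F1_female_test", treatment,
                 np.where(mated, "yes", "no"), False,
                 total, females, total - females)


def _backcross_group(cfg, seed, female_strain, origin_pair, treatment,
                     direction):
    spec = cfg.strains[female_strain]
    hybrid = direction is not None
    dp = cfg.direction_params(direction) if hybrid else DirectionParams()
    origin = cross_label(*origin_pair)
    rng = _substream(seed, f"F2|{female_strain}|{origin}|{treatment}")
    n = cfg.n_rep
    p = spec.p_mate * (dp.male_behaviour if hybrid else 1.0)
    mated = rng.random(n) < min(p, 1.0)
    total = _draw_counts(rng, spec.mu, spec.k, n)
    s = spec.s_f * (dp.male_fertility if hybrid else 1.0)
    females = np.where(mated, rng.binomial(total, min(s, 1.0)), 0)
    return _rows(female_strain, origin, origin, "F2_male_backcross",
                 treatment, np.where(mated, "yes", "no"), False,
                 total, females, total - females)


def _rows(fs, ms, origin, generation, treatment, mating, virgin,
          total, females, males):
    n = len(total)
    mating = np.asarray(mating, dtype=object)
    return [("", fs, ms, origin, generation, treatment, str(mating[i]),
             bool(virgin), int(total[i]), int(females[i]), int(males[i]),
             "-")
            for i in range(n)]


# ---------------------------------------------------------------------------
# closed-form expected RI

def true_ri(cfg: SimulationConfig, barrier: Barrier,
            direction: tuple[str, str],
            ci_variant: str = "not_applicable") -> float:
    """Model-implied expected RI for one barrier and direction.

    Uses the same outcome metrics as the estimation pipeline: expected
    proportions for occurrence metrics and zero-truncated means for
    conditional count metrics. NaN for the qualitative ecological
    annotation.
    """
    barrier = Barrier(barrier)
    F, M = direction
    spec = cfg.strains[F]
    dp = cfg.direction_params(direction)
    mu, k, s = spec.mu, spec.k, spec.s_f
    if barrier is Barrier.ECOLOGICAL:
        return math.nan
    if barrier is Barrier.SEXUAL:
        return ri_index(cfg.inter_p_mate(direction), spec.p_mate)
    if barrier is Barrier.FEMALE_INVIABILITY:
        m_h = mu * s * dp.female_viability
        if ci_variant == "with_CI":
            c = (cfg.ci_penetrance
                 if cfg.ci_applies(F, M, treated=False) else 0.0)
            if cfg.ci_mode == "all_or_nothing":
                H = cfg.inter_p_mate(direction) * (1 - c) * (1 - _p_zero(m_h, k))
            else:
                H = cfg.inter_p_mate(direction) * (1 - _p_zero(m_h * (1 - c), k))
            C = spec.p_mate * (1 - _p_zero(mu * s, k))
            return ri_index(H, C)
        return ri_index(_cond_mean(m_h, k), _cond_mean(mu * s, k))
    if barrier is Barrier.FEMALE_BEHAV_STERILITY:
        return ri_index(spec.p_mate * dp.female_behaviour, spec.p_mate)
    if barrier is Barrier.FEMALE_PHYS_STERILITY:
        return ri_index(1 - _p_zero(mu * dp.female_fertility, k),
                        1 - _p_zero(mu, k))
    if barrier is Barrier.FEMALE_REDUCED_FERTILITY:
        return ri_index(_cond_mean(mu * dp.female_fertility, k),
                        _cond_mean(mu, k))
    if barrier is Barrier.MALE_INVIABILITY:
        return ri_index(_cond_mean(mu * dp.male_viability, k),
                        _cond_mean(mu, k))
    # averaged backcross barriers
    ris = []
    for S in (F, M):
        sp = cfg.strains[S]
        if barrier is Barrier.MALE_BEHAV_STERILITY:
            ris.append(ri_index(sp.p_mate * dp.male_behaviour, sp.p_mate))
        elif barrier is Barrier.MALE_PHYS_STERILITY:
            H = sp.p_mate * dp.male_behaviour * (
                1 - _p_zero(sp.mu * sp.s_f * dp.male_fertility, sp.k))
            C = sp.p_mate * (1 - _p_zero(sp.mu * sp.s_f, sp.k))
            ris.append(ri_index(H, C))
        elif barrier is Barrier.MALE_REDUCED_FERTILITY:
            ris.append(ri_index(
                _cond_mean(sp.mu * sp.s_f * dp.male_fertility, sp.k),
                _cond_mean(sp.mu * sp.s_f, sp.k)))
        else:
            raise ValueError(f"barrier {barrier} not parameterised")
    return float(np.mean(ris))


# ---------------------------------------------------------------------------
# alignment simulation

def simulate_alignment(n_per_clade: int, length: int = 658,
                       between_divergence: float | Mapping = 0.10,
                       within_divergence: float = 0.0,
                       seed: int = 0,
                       clade_names: Sequence[str] | None = None
                       ) -> Alignment:
    """Simulate clade-structured aligned sequences at target divergences.

    Sequences evolve from a random root on a star tree of clade
    ancestors with Jukes-Cantor-style site flipping (a flipped site
    takes one of the three other bases uniformly). Branch flip
    fractions are calibrated so the *expected* pairwise p-distance
    between leaves of two clades equals the requested target: along a
    path the "identity factors" g = 1 - (4/3) f multiply, so expected
    distance d satisfies 1 - (4/3) d = prod(g). ``between_divergence``
    is a scalar (all clade pairs alike) or a mapping
    ``{(cladeA, cladeB): target}``; per-clade branch lengths are then
    solved by least squares in log-g space.
    """
    if isinstance(between_divergence, Mapping):
        targets = {frozenset(k): float(v)
                   for k, v in between_divergence.items()}
        names = clade_names or sorted({c for k in between_divergence for c in k})
    else:
        names = list(clade_names) if clade_names else ["A", "B"]
        targets = {frozenset(p): float(between_divergence)
                   for p in combinations(names, 2)}
    for t in list(targets.values()) + [within_divergence]:
        if not 0.0 <= t < 0.75:
            raise ValueError(f"divergence target out of [0, 0.75): {t}")

    g_within = math.sqrt(1.0 - 4.0 * within_divergence / 3.0)
    f_within = 0.75 * (1.0 - g_within)
    g_clade = _solve_clade_branches(names, targets, g_within)

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    root = rng.choice(bases, size=length)

    def mutate(seq: np.ndarray, f: float) -> np.ndarray:
        out = seq.copy()
        hit = np.flatnonzero(rng.random(length) < f)
        if len(hit):
            # shift by 1..3 in base order: uniform over the other bases
            idx = np.searchsorted(bases, out[hit])
            out[hit] = bases[(idx + rng.integers(1, 4, len(hit))) % 4]
        return out

    taxa, seqs, clade_of = [], [], {}
    for name in names:
        f_branch = 0.75 * (1.0 - g_clade[name])
        ancestor = mutate(root, f_branch)
        for i in range(n_per_clade):
            label = f"{name}_{i + 1}"
            taxa.append(label)
            seqs.append(mutate(ancestor, f_within).tobytes().decode("ascii"))
            clade_of[label] = name
    return Alignment(taxa=taxa, sequences=seqs, clade_of=clade_of)


def _solve_clade_branches(names, targets, g_within) -> dict[str, float]:
    """Least-squares log-g branch factors reproducing pair targets."""
    if len(names) == 1:
        return {names[0]: 1.0}
    pairs = [p for p in combinations(names, 2) if frozenset(p) in targets]
    A = np.zeros((len(pairs), len(names)))
    b = np.zeros(len(pairs))
    for row, (x, y) in enumerate(pairs):
        A[row, names.index(x)] = A[row, names.index(y)] = 1.0
        t = targets[frozenset((x, y))]
        # leaf branches contribute g_within^2 to every between-clade path
        val = (1.0 - 4.0 * t / 3.0) / (g_within ** 2)
        if val <= 0:
            raise ValueError(
                f"targets for pair {x},{y} unreachable given within-clade "
                f"divergence")
        b[row] = math.log(val)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return {n: min(1.0, math.exp(s)) for n, s in zip(names, sol)}
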