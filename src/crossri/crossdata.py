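"""Data model and I/O for crossing-experiment replicate records.

One :class:`CrossRecord` is a single replicate cross: a female of one
strain paired with a male of another (or the same) strain, the observed
mating outcome, and the sexed offspring counts. Records from three
experimental stages share the schema:

``P``
    parental-generation cross between (possibly tetracycline-treated)
    strain individuals.
``F1_female_test``
    a test of an F1 female (hybrid or non-hybrid, identified by
    ``female_origin``) — either a mating trial with a parental-type
    male, an oviposition trial after mating, or a virgin oviposition
    trial (``virgin_female=True``; haplodiploid arrhenotoky means such
    females produce sons only).
``F2_male_backcross``
    a backcross of an F2 male to a parental-type female.
    ``female_origin`` names the parental cross of the tested male's
    mother (the F1 female from whose unfertilised eggs he developed),
    i.e. the provenance of the hybrid line under test; ``female_strain``
    is the strain of the parental-type female partner.

The on-disk format is a UTF-8 tab-separated table with one replicate
per row and ``-`` for missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENERATIONS = ("P", "F1_female_test", "F2_male_backcross")
TREATMENTS = ("untreated", "tetracycline")
MATING_STATES = ("yes", "no", "not_observed")

#: mandatory columns of the cross-record table, in canonical order
COLUMNS = (
    "cross_id", "female_strain", "male_strain", "female_origin",
    "generation", "treatment", "mating_observed", "virgin_female",
    "n_offspring_total", "n_offspring_female", "n_offspring_male",
    "host",
)

MISSING = "-"


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable header."""


class RecordError(ValueError):
    """A row violates the record invariants."""


def cross_label(female_strain: str, male_strain: str) -> str:
    """Canonical label of a cross, female first: ``"BIR♀×STU♂"``."""
    return f"{female_strain}♀×{male_strain}♂"


@dataclass(frozen=True)
class CrossRecord:
    """One replicate cross and its outcome."""

    cross_id: str
    female_strain: str
    male_strain: str
    female_origin: str = "parental"
    generation: str = "P"
    treatment: str = "untreated"
    mating_observed: str = "not_observed"
    virgin_female: bool = False
    n_offspring_total: int = 0
    n_offspring_female: int = 0
    n_offspring_male: int = 0
    host: str = MISSING

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise RecordError(
                f"{self.cross_id}: unknown generation {self.generation!r}")
        if self.treatment not in TREATMENTS:
            raise RecordError(
                f"{self.cross_id}: unknown treatment {self.treatment!r}")
        if self.mating_observed not in MATING_STATES:
            raise RecordError(
                f"{self.cross_id}: unknown mating state "
                f"{self.mating_observed!r}")
        for name in ("n_offspring_total", "n_offspring_female",
                     "n_offspring_male"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise RecordError(
                    f"{self.cross_id}: {name} must be a non-negative "
                    f"integer, got {v!r}")
        if self.n_offspring_female + self.n_offspring_male > self.n_offspring_total:
            raise RecordError(
                f"{self.cross_id}: sexed offspring "
                f"({self.n_offspring_female}F + {self.n_offspring_male}M) "
                f"exceed total {self.n_offspring_total}")
        if self.virgin_female and self.n_offspring_female > 0:
            # virgin females lay only unfertilised (male) eggs
            raise RecordError(
                f"{self.cross_id}: virgin female cannot have female "
                f"offspring (arrhenotoky)")


class CrossSet:
    """An ordered collection of :class:`CrossRecord` with unique ids.

    Internally frame-backed for vectorised grouping; ``records`` yields
    dataclass views.
    """

    def __init__(self, records: Iterable[CrossRecord] | pd.DataFrame,
                 metadata: dict | None = None, validate: bool = True):
        if isinstance(records, pd.DataFrame):
            frame = records.reset_index(drop=True).copy()
        else:
            recs = list(records)
            frame = pd.DataFrame(
                [[getattr(r, c) for c in COLUMNS] for r in recs],
                columns=list(COLUMNS))
            validate = False  # dataclass __post_init__ already checked
            if frame.empty:
                frame = pd.DataFrame(columns=list(COLUMNS))
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        self._frame = frame[list(COLUMNS)].copy()
        self.metadata = dict(metadata or {})
        if validate and len(self._frame):
            self._validate_frame()
        dup = self._frame["cross_id"][self._frame["cross_id"].duplicated()]
        if len(dup):
            raise RecordError(f"duplicate cross_id(s): {sorted(set(dup))}")
        self._warn_missing_controls()

    def _validate_frame(self) -> None:
        f = self._frame
        for name in ("n_offspring_total", "n_offspring_female",
                     "n_offspring_male"):
            col = pd.to_numeric(f[name], errors="raise")
            if (col < 0).any() or (col != col.astype(int)).any():
                bad = f.loc[(col < 0) | (col != col.astype(int)), "cross_id"]
                raise RecordError(
                    f"non-negative integer required for {name} "
                    f"(rows {list(bad)})")
            f[name] = col.astype(int)
        f["virgin_female"] = f["virgin_female"].astype(bool)
        bad = f["n_offspring_female"] + f["n_offspring_male"] > f["n_offspring_total"]
        if bad.any():
            raise RecordError(
                "sexed offspring exceed total in rows "
                f"{list(f.loc[bad, 'cross_id'])}")
        bad = f["virgin_female"] & (f["n_offspring_female"] > 0)
        if bad.any():
            raise RecordError(
                "virgin female with female offspring (arrhenotoky) in rows "
                f"{list(f.loc[bad, 'cross_id'])}")
        for name, allowed in (("generation", GENERATIONS),
                              ("treatment", TREATMENTS),
                              ("mating_observed", MATING_STATES)):
            bad = ~f[name].isin(allowed)
            if bad.any():
                raise RecordError(
                    f"unknown {name} value(s) "
                    f"{sorted(set(f.loc[bad, name]))}")

    def _warn_missing_controls(self) -> None:
        f = self._frame
        p = f[f["generation"] == "P"]
        if p.empty:
            return
        inter = p[p["female_strain"] != p["male_strain"]]
        control_females = set(
            p.loc[p["female_strain"] == p["male_strain"], "female_strain"])
        for fs in sorted(set(inter["female_strain"]) - control_females):
            logger.warning(
                "no intrastrain control crosses for female strain %r", fs)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[CrossRecord]:
        for row in self._frame.itertuples(index=False):
            yield CrossRecord(*row)

    @property
    def records(self) -> list[CrossRecord]:
        return list(self)

    def to_frame(self) -> pd.DataFrame:
        """Return a copy of the underlying record table."""
        return self._frame.copy()

    def subset(self, mask) -> "CrossSet":
        return CrossSet(self._frame[mask], metadata=self.metadata,
                        validate=False)

    def __eq__(self, other) -> bool:
        return (isinstance(other, CrossSet)
                and self._frame.equals(other._frame))


# ---------------------------------------------------------------------------
# I/O

def read_cross_table(path, strict: bool = True) -> CrossSet:
    """Read a tab-separated cross-record table.

    Unknown columns are preserved in ``metadata["extra_columns"]``.
    With ``strict=False`` rows violating record invariants are skipped
    with a logged warning instead of raising.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING],
                      keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s): {missing}")
    extra = [c for c in raw.columns if c not in COLUMNS]
    records: list[CrossRecord] = []
    skipped = 0
    for i, row in raw.iterrows():
        try:
            records.append(_record_from_row(row, i))
        except (RecordError, ValueError) as exc:
            if strict:
                raise RecordError(f"{path} row {i + 2}: {exc}") from exc
            skipped += 1
            logger.warning("%s row %d skipped: %s", path, i + 2, exc)
    meta = {"source": str(path), "n_skipped_rows": skipped}
    if extra:
        meta["extra_columns"] = raw[extra].to_dict("list")
    return CrossSet(records, metadata=meta)


def _record_from_row(row: pd.Series, idx: int) -> CrossRecord:
    def get(name, default=None):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            if default is None:
                raise RecordError(f"missing value for {name}")
            return default
        return v

    def as_count(name):
        v = get(name, "0")
        try:
            fv = float(v)
        except ValueError:
            raise RecordError(f"non-integer count for {name}: {v!r}")
        if fv != int(fv):
            raise RecordError(f"non-integer count for {name}: {v!r}")
        return int(fv)

    virgin = str(get("virgin_female", "false")).strip().lower()
    if virgin not in ("true", "false", "1", "0", "yes", "no"):
        raise RecordError(f"unparseable virgin_female flag {virgin!r}")
    return CrossRecord(
        cross_id=str(get("cross_id", f"row{idx + 2}")),
        female_strain=str(get("female_strain")),
        male_strain=str(get("male_strain", MISSING)),
        female_origin=str(get("female_origin", "parental")),
        generation=str(get("generation", "P")),
        treatment=str(get("treatment", "untreated")),
        mating_observed=str(get("mating_observed", "not_observed")),
        virgin_female=virgin in ("true", "1", "yes"),
        n_offspring_total=as_count("n_offspring_total"),
        n_offspring_female=as_count("n_offspring_female"),
        n_offspring_male=as_count("n_offspring_male"),
        host=str(get("host", MISSING)),
    )


def write_cross_table(cs: CrossSet, path) -> None:
    """Write a CrossSet as the canonical UTF-8 TSV."""
    frame = cs.to_frame()
    frame["virgin_female"] = np.where(frame["virgin_female"], "true", "false")
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Per-group outcome summaries

def group_outcomes(cs: CrossSet, by: Sequence[str]) -> pd.DataFrame:
    """Summarise outcomes per group of replicate crosses.

    Returns one row per group with

    ``n``                        replicates in the group
    ``n_mating_assessed``        replicates where mating was recorded
    ``prop_copulation``          share of assessed replicates that mated
    ``n_with_female_offspring``  replicates with >=1 female offspring
    ``prop_female_offspring``    occurrence of female offspring over all
                                 replicates, in percent
    ``prop_any_offspring``       occurrence of any offspring, in percent
    ``mean_offspring_total`` / ``mean_offspring_female`` /
    ``mean_offspring_male``      means over offspring-bearing replicates
                                 only (NaN when no replicate bears the
                                 respective offspring)

    Occurrence metrics use all replicates as denominator; means
    deliberately condition on replicates with offspring. Empty groups
    are flagged with ``n=0`` and NaN proportions, never dropped.
    """
    bad = [k for k in by if k not in COLUMNS]
    if bad:
        raise KeyError(f"unknown grouping key(s): {bad}")
    f = cs.to_frame()
    rows = []
    if f.empty:
        return pd.DataFrame(columns=list(by) + _SUMMARY_COLS)
    for key, g in f.groupby(list(by), sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        rows.append(dict(zip(by, key)) | _summarise(g))
    return pd.DataFrame(rows)


_SUMMARY_COLS = [
    "n", "n_mating_assessed", "prop_copulation",
    "n_with_female_offspring", "prop_female_offspring",
    "prop_any_offspring", "mean_offspring_total",
    "mean_offspring_female", "mean_offspring_male",
]


def _summarise(g: pd.DataFrame) -> dict:
    n = len(g)
    assessed = g[g["mating_observed"] != "not_observed"]
    with_f = int((g["n_offspring_female"] >= 1).sum())
    with_any = int((g["n_offspring_total"] >= 1).sum())
    bearing = g[g["n_offspring_total"] >= 1]
    bearing_f = g[g["n_offspring_female"] >= 1]
    bearing_m = g[g["n_offspring_male"] >= 1]
    return {
        "n": n,
        "n_mating_assessed": len(assessed),
        "prop_copulation": (100.0 * (assessed["mating_observed"] == "yes").mean()
                            if len(assessed) else np.nan),
        "n_with_female_offspring": with_f,
        "prop_female_offspring": 100.0 * with_f / n if n else np.nan,
        "prop_any_offspring": 100.0 * with_any / n if n else np.nan,
        "mean_offspring_total": (bearing["n_offspring_total"].mean()
                                 if len(bearing) else np.nan),
        "mean_offspring_female": (bearing_f["n_offspring_female"].mean()
                                  if len(bearing_f) else np.nan),
        "mean_offspring_male": (bearing_m["n_offspring_male"].mean()
                                if len(bearing_m) else np.nan),
    }


# ---------------------------------------------------------------------------
# Sperm counts

SPERM_SOURCES = ("seminal_vesicle", "spermatheca")


def estimate_sperm_total(spot_counts: Sequence[int], source: str) -> float:
    """Estimate total sperm cells from three random spot counts.

    Three of eight air-dried spots of the 20-uL sperm suspension are
    counted; the sum is scaled by 20 (total volume) and divided by 3
    (spots counted). Seminal-vesicle values are doubled because only one
    of the male's two vesicles is opened.
    """
    if source not in SPERM_SOURCES:
        raise ValueError(f"unknown source {source!r}; one of {SPERM_SOURCES}")
    counts = list(spot_counts)
    if len(counts) != 3:
        raise ValueError(f"exactly three spot counts required, got {len(counts)}")
    for c in counts:
        if not float(c).is_integer() or c < 0:
            raise ValueError(f"spot counts must be non-negative integers: {c!r}")
    total = sum(counts) * 20.0 / 3.0
    if source == "seminal_vesicle":
        total *= 2.0
    return total


@dataclass(frozen=True)
class SpermSample:
    """One dissected sperm-count sample (three counted spots)."""

    sample_id: str
    source: str
    parental_cross: str
    spot_counts: tuple[int, int, int]
    estimated_total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = estimate_sperm_total(self.spot_counts, self.source)
        if self.estimated_total is None:
            object.__setattr__(self, "estimated_total", expected)
        elif abs(self.estimated_total - expected) > 1e-9:
            raise RecordError(
                f"{self.sample_id}: estimated_total {self.estimated_total} "
                f"does not reproduce the spot formula ({expected})")


def read_sperm_table(path) -> list[SpermSample]:
    """Read a sperm-sample TSV (sample_id, source, parental_cross, spot1-3)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["sample_id", "source", "parental_cross", "spot1", "spot2", "spot3"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {missing}")
    samples = []
    for _, row in raw.iterrows():
        spots = tuple(int(row[f"spot{i}"]) for i in (1, 2, 3))
        samples.append(SpermSample(
            sample_id=str(row["sample_id"]), source=str(row["source"]),
            parental_cross=str(row["parental_cross"]), spot_counts=spots))
    return samples
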