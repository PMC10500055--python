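"""Uncorrected p-distances, barcode-gap delimitation and BSC concordance.

The barcode analysis works on a pre-built nucleotide alignment (COI
barcode region). Distances are uncorrected proportions of mismatching
sites; sites with a gap or IUPAC ambiguity code in either sequence are
excluded under pairwise deletion (the default), or in any sequence under
complete deletion. Fixed-threshold delimitation is single-linkage: two
taxa belong to one cluster iff they are connected by a chain of
pairwise distances below the threshold (2% and 2.2% are the common COI
conventions). The resulting partition is scored against the partition
implied by total reproductive isolation (the biological species
concept): a pair is conspecific iff total isolation stays below a
threshold in both directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

VALID_BASES = frozenset(b"ACGT")


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with unique taxon labels."""

    taxa: list[str]
    sequences: list[str]
    clade_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """(n_taxa, length) uint8 array of uppercase sequence bytes."""
        return np.frombuffer(
            "".join(s.upper() for s in self.sequences).encode("ascii"),
            dtype=np.uint8).reshape(len(self.taxa), self.length)


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read a pre-aligned sequence file (FASTA by default)."""
    from Bio import AlignIO
    aln = AlignIO.read(path, fmt)
    return Alignment(taxa=[rec.id for rec in aln],
                     sequences=[str(rec.seq) for rec in aln])


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{name}\n{seq}\n")


def p_distance(a: str, b: str, policy: str = "pairwise") -> float:
    """Uncorrected pairwise distance: mismatches / compared sites.

    Sites where either sequence carries a gap or an ambiguity code are
    excluded (pairwise deletion). NaN when no site is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if policy not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {policy!r}")
    aa = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    valid_tbl = np.zeros(256, dtype=bool)
    valid_tbl[list(VALID_BASES)] = True
    mask = valid_tbl[aa] & valid_tbl[bb]
    n = int(mask.sum())
    if n == 0:
        return math.nan
    return float((aa[mask] != bb[mask]).sum() / n)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distance proportions."""

    taxa: list[str]
    d: np.ndarray
    clade_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n},{n})")
        finite = self.d[np.isfinite(self.d)]
        if np.any(finite < -1e-12) or np.any(finite > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")
        if not np.allclose(np.nan_to_num(self.d),
                           np.nan_to_num(self.d.T), atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("non-zero diagonal")
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)

    def write_phylip(self, path) -> None:
        """PHYLIP square distance matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for name, row in zip(self.taxa, self.d):
                cells = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{name:<10s} {cells}\n")

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def distance_matrix(aln: Alignment, policy: str = "pairwise"
                    ) -> DistanceMatrix:
    """All pairwise uncorrected distances of an alignment."""
    if policy not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {policy!r}")
    arr = aln.to_array()
    valid_tbl = np.zeros(256, dtype=bool)
    valid_tbl[list(VALID_BASES)] = True
    valid = valid_tbl[arr]
    if policy == "complete":
        keep = valid.all(axis=0)
        arr, valid = arr[:, keep], valid[:, keep]
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        m = int(both.sum())
        d[i, j] = d[j, i] = (
            (arr[i, both] != arr[j, both]).sum() / m if m else math.nan)
    return DistanceMatrix(taxa=list(aln.taxa), d=d,
                          clade_of=dict(aln.clade_of) if aln.clade_of else None)


def clade_mean_distance(dm: DistanceMatrix, clade_a: str,
                        clade_b: str | None = None) -> float:
    """Mean pairwise distance between (or within) clades.

    Within-clade means average over unordered pairs; a singleton clade
    has no within-clade pairs and yields NaN.
    """
    if dm.clade_of is None:
        raise ValueError("distance matrix carries no clade labels")
    clade_b = clade_b if clade_b is not None else clade_a
    ia = [dm._index[t] for t, c in dm.clade_of.items() if c == clade_a]
    ib = [dm._index[t] for t, c in dm.clade_of.items() if c == clade_b]
    if not ia or not ib:
        raise ValueError(f"empty clade among {clade_a!r}, {clade_b!r}")
    if clade_a == clade_b:
        if len(ia) < 2:
            return math.nan
        pairs = [dm.d[i, j] for i, j in combinations(ia, 2)]
    else:
        pairs = [dm.d[i, j] for i in ia for j in ib]
    return float(np.nanmean(pairs))


# ---------------------------------------------------------------------------
# delimitation

def threshold_delimit(dm: DistanceMatrix, threshold: float
                      ) -> dict[str, int]:
    """Single-linkage clustering at a fixed distance threshold.

    Taxa are joined iff connected by a chain of pairwise distances
    strictly below ``threshold``. Cluster ids are 0-based and ordered by
    first taxon occurrence, so the output is invariant to input order
    up to the taxon list itself.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1): {threshold}")
    with np.errstate(invalid="ignore"):
        adj = csr_matrix((dm.d < threshold).astype(np.int8))
    _, labels = connected_components(adj, directed=False)
    return _canonical_labels(dm.taxa, labels)


def _canonical_labels(taxa: Sequence[str], labels: Sequence[int]
                      ) -> dict[str, int]:
    remap: dict[int, int] = {}
    out = {}
    for t, lab in zip(taxa, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[t] = remap[lab]
    return out


def bsc_partition(taxa: Sequence[str],
                  isolation: Mapping[tuple[str, str], float],
                  threshold: float = 0.8) -> dict[str, int]:
    """Partition taxa by total reproductive isolation (BSC verdicts).

    ``isolation`` maps ordered strain pairs to total isolation T; a pair
    is conspecific iff ``max(T_ab, T_ba) < threshold`` — isolation in
    one direction suffices to restrict gene flow. Pairs without any T
    entry are treated as split (no evidence of interbreeding).
    Conspecificity is closed transitively.
    """
    taxa = list(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    adj = np.zeros((n, n), dtype=np.int8)
    for a, b in combinations(taxa, 2):
        ts = [t for key in ((a, b), (b, a))
              if (t := isolation.get(key)) is not None]
        if ts and max(ts) < threshold:
            adj[index[a], index[b]] = adj[index[b], index[a]] = 1
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return _canonical_labels(taxa, labels)


@dataclass
class ConcordanceReport:
    """Pairwise agreement of a barcode partition with BSC verdicts."""

    n_pairs: int
    both_lumped: int
    both_split: int
    barcode_split_bsc_lumped: list[tuple[str, str]]
    barcode_lumped_bsc_split: list[tuple[str, str]]
    rand_index: float
    conflicts: list[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.conflicts = sorted(self.barcode_split_bsc_lumped
                                + self.barcode_lumped_bsc_split)

    @property
    def concordant(self) -> bool:
        return not self.conflicts


def compare_delimitations(barcode_clusters: Mapping[str, int],
                          bsc_species: Mapping[str, int]
                          ) -> ConcordanceReport:
    """Score a barcode partition against the BSC partition.

    Both partitions must cover the same taxa. Agreement is per unordered
    pair — lumped by both, split by both, or in conflict — and
    summarised by the Rand index (share of pairs on which the two
    partitions agree).
    """
    if set(barcode_clusters) != set(bsc_species):
        raise ValueError(
            "partitions cover different taxa: "
            f"{sorted(set(barcode_clusters) ^ set(bsc_species))}")
    taxa = sorted(barcode_clusters)
    both_lumped = both_split = 0
    split_lumped, lumped_split = [], []
    for a, b in combinations(taxa, 2):
        bc_same = barcode_clusters[a] == barcode_clusters[b]
        bsc_same = bsc_species[a] == bsc_species[b]
        if bc_same and bsc_same:
            both_lumped += 1
        elif not bc_same and not bsc_same:
            both_split += 1
        elif not bc_same and bsc_same:
            split_lumped.append((a, b))
        else:
            lumped_split.append((a, b))
    n_pairs = len(taxa) * (len(taxa) - 1) // 2
    rand = ((both_lumped + both_split) / n_pairs) if n_pairs else 1.0
    return ConcordanceReport(
        n_pairs=n_pairs, both_lumped=both_lumped, both_split=both_split,
        barcode_split_bsc_lumped=split_lumped,
        barcode_lumped_bsc_split=lumped_split,
        rand_index=rand)
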