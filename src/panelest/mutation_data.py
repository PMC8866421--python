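"""Reading annotated mutation data and building per-sample count tensors.

Mutation calls arrive as MAF-style tab-separated files (one annotated
somatic variant per row).  Only three columns are consumed: the sample
barcode, the gene symbol and the variant classification; everything else
in the file is ignored.  Raw variant classifications are collapsed into a
small set of variant *groups* (by default ``indel`` for frameshift
insertions/deletions and ``other`` for the remaining non-synonymous
classes), and counts are aggregated into a dense sample x gene x group
tensor.  Exome-wide biomarkers such as TMB and TIB are sums of that
tensor over a chosen subset of groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel group for variant classes (synonymous etc.) that never enter S.
EXCLUDED = "__excluded__"

#: The seven non-synonymous variant classifications retained by default,
#: split into frameshift indels versus everything else.
DEFAULT_GROUPS: dict[str, str] = {
    "Frame_Shift_Del": "indel",
    "Frame_Shift_Ins": "indel",
    "Missense_Mutation": "other",
    "Nonsense_Mutation": "other",
    "Splice_Site": "other",
    "In_Frame_Del": "other",
    "In_Frame_Ins": "other",
    "Nonstop_Mutation": "other",
    "Translation_Start_Site": "other",
    "Silent": EXCLUDED,
    "3'UTR": EXCLUDED,
    "5'UTR": EXCLUDED,
    "3'Flank": EXCLUDED,
    "5'Flank": EXCLUDED,
    "Intron": EXCLUDED,
    "IGR": EXCLUDED,
    "RNA": EXCLUDED,
}


class MafFormatError(ValueError):
    """Raised when a MAF-style file lacks a required column."""


@dataclass(frozen=True)
class VariantCatalog:
    """Mapping from raw variant classifications to model variant groups.

    Parameters
    ----------
    groups
        Mapping raw classification label -> group label.  Labels mapped to
        :data:`EXCLUDED` are tagged but never counted.
    reference_group
        The group ``s1`` whose gene-by-group effects are pinned to zero
        for identifiability.
    """

    groups: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    reference_group: str = "other"

    def __post_init__(self) -> None:
        if self.reference_group not in self.group_labels:
            raise ValueError(
                f"reference_group {self.reference_group!r} not among groups "
                f"{self.group_labels}"
            )

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Ordered non-excluded group labels (the set S), reference first."""
        seen: list[str] = []
        for g in self.groups.values():
            if g != EXCLUDED and g not in seen:
                seen.append(g)
        ref = [g for g in seen if g == self.reference_group]
        rest = [g for g in seen if g != self.reference_group]
        return tuple(ref + rest)

    def group_of(self, variant_class: str) -> str:
        """Group label for a raw classification; unknown classes are excluded."""
        return self.groups.get(variant_class, EXCLUDED)


@dataclass(frozen=True)
class GeneCatalog:
    """Ordered gene identifiers with coding lengths in bases."""

    genes: tuple[str, ...]
    lengths: np.ndarray  # int, bases, aligned with ``genes``

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("gene identifiers must be unique")
        if lengths.shape != (len(self.genes),):
            raise ValueError("lengths must align with genes")
        if np.any(lengths <= 0):
            raise ValueError("gene lengths must be strictly positive")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    @property
    def total_length(self) -> float:
        """Total coding length of the whole gene set (l_G)."""
        return float(self.lengths.sum())

    def length_of(self, genes: Iterable[str]) -> float:
        """Summed coding length l_P of a subset of genes."""
        return float(sum(self.lengths[self._index[g]] for g in genes))

    @classmethod
    def from_table(cls, path: str | Path, gene_col: str = "gene",
                   length_col: str = "length_bases") -> "GeneCatalog":
        """Read a gene-length TSV with columns ``gene`` and ``length_bases``."""
        df = pd.read_csv(path, sep="\t")
        for col in (gene_col, length_col):
            if col not in df.columns:
                raise MafFormatError(f"gene length table missing column {col!r}")
        return cls(tuple(df[gene_col].astype(str)), df[length_col].to_numpy(float))

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame({"gene": self.genes, "length_bases": self.lengths.astype(int)}
                     ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MutationRecord:
    """One annotated somatic variant call (one MAF row)."""

    sample_id: str
    gene: str
    variant_class: str
    group: str  # resolved group label, possibly EXCLUDED
    chromosome: str | None = None
    position: int | None = None

    @property
    def excluded(self) -> bool:
        return self.group == EXCLUDED


@dataclass(frozen=True)
class BiomarkerSpec:
    """An exome-wide biomarker: a sum of counts over target variant groups.

    ``name`` is a label (e.g. ``"TMB"``), ``target_groups`` the subset
    S-bar of variant groups that constitute the biomarker, and
    ``class_threshold`` the cutoff defining the high-biomarker class
    (inclusive: high iff value >= threshold).
    """

    name: str
    target_groups: tuple[str, ...]
    class_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.target_groups:
            raise ValueError("target_groups must be non-empty")
        if self.class_threshold < 0:
            raise ValueError("class_threshold must be >= 0")


def tmb_spec(catalog: VariantCatalog, threshold: float = 300.0) -> BiomarkerSpec:
    """TMB: all non-synonymous groups; high class at >= 300 exome mutations."""
    return BiomarkerSpec("TMB", catalog.group_labels, threshold)


def tib_spec(catalog: VariantCatalog, threshold: float = 10.0,
             indel_group: str = "indel") -> BiomarkerSpec:
    """TIB: frameshift indel group only; high class at >= 10 indels."""
    if indel_group not in catalog.group_labels:
        raise ValueError(f"group {indel_group!r} not in catalog")
    return BiomarkerSpec("TIB", (indel_group,), threshold)


@dataclass(frozen=True)
class CountTensor:
    """Non-negative mutation counts indexed (sample, gene, group)."""

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    groups: tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_genes, n_groups)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        expected = (len(self.samples), len(self.genes), len(self.groups))
        if counts.shape != expected:
            raise ValueError(f"counts shape {counts.shape} != {expected}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown variant group {group!r}") from None

    def subset_samples(self, samples: Sequence[str]) -> "CountTensor":
        idx = [self.samples.index(s) for s in samples]
        return CountTensor(tuple(samples), self.genes, self.groups,
                           self.counts[idx])

    # -- long-format TSV round trip -------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write non-zero cells in long format plus an index sidecar.

        The sidecar (``<path>.index.json``-style TSV is avoided; instead a
        companion ``<path>.index`` TSV records the full sample/gene/group
        orderings so all-zero rows survive the round trip).
        """
        path = Path(path)
        i, g, s = np.nonzero(self.counts)
        pd.DataFrame({
            "sample": [self.samples[k] for k in i],
            "gene": [self.genes[k] for k in g],
            "group": [self.groups[k] for k in s],
            "count": self.counts[i, g, s],
        }).to_csv(path, sep="\t", index=False)
        index = pd.DataFrame({
            "kind": (["sample"] * len(self.samples) + ["gene"] * len(self.genes)
                     + ["group"] * len(self.groups)),
            "label": list(self.samples) + list(self.genes) + list(self.groups),
        })
        index.to_csv(path.with_suffix(path.suffix + ".index"), sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTensor":
        path = Path(path)
        long = pd.read_csv(path, sep="\t")
        index = pd.read_csv(path.with_suffix(path.suffix + ".index"), sep="\t")
        samples = tuple(index.loc[index["kind"] == "sample", "label"].astype(str))
        genes = tuple(index.loc[index["kind"] == "gene", "label"].astype(str))
        groups = tuple(index.loc[index["kind"] == "group", "label"].astype(str))
        counts = np.zeros((len(samples), len(genes), len(groups)), dtype=np.int64)
        si = {v: k for k, v in enumerate(samples)}
        gi = {v: k for k, v in enumerate(genes)}
        ri = {v: k for k, v in enumerate(groups)}
        for row in long.itertuples(index=False):
            counts[si[str(row.sample)], gi[str(row.gene)], ri[str(row.group)]] += row.count
        return cls(samples, genes, groups, counts)


def read_maf(
    path: str | Path,
    variant_catalog: VariantCatalog | None = None,
    *,
    sample_col: str = "Tumor_Sample_Barcode",
    gene_col: str = "Hugo_Symbol",
    class_col: str = "Variant_Classification",
) -> list[MutationRecord]:
    """Read a MAF-style TSV into mutation records.

    Rows whose classification maps to the excluded sentinel are retained
    but tagged, so downstream aggregation can skip them while callers can
    still audit what was dropped.  Malformed rows (missing any of the
    three required fields) are reported with their line numbers and
    skipped.
    """
    catalog = variant_catalog or VariantCatalog()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, na_values=[""])
    for col in (sample_col, gene_col, class_col):
        if col not in df.columns:
            raise MafFormatError(f"MAF file {path} missing required column {col!r}")
    if df.empty:
        warnings.warn(f"MAF file {path} contains no data rows", stacklevel=2)
        return []
    records: list[MutationRecord] = []
    bad = df[[sample_col, gene_col, class_col]].isna().any(axis=1)
    for line in df.index[bad]:
        logger.warning("skipping malformed MAF row at data line %d", line + 2)
    sub = df.loc[~bad, [sample_col, gene_col, class_col]]
    for sample, gene, vclass in sub.itertuples(index=False):
        records.append(MutationRecord(
            sample_id=str(sample), gene=str(gene), variant_class=str(vclass),
            group=catalog.group_of(str(vclass))))
    return records


def aggregate_counts(
    records: Sequence[MutationRecord],
    genes: GeneCatalog,
    variants: VariantCatalog | None = None,
    *,
    samples: Sequence[str] | None = None,
    unknown_gene: str = "warn",
) -> CountTensor:
    """Aggregate mutation records into a sample x gene x group count tensor.

    Excluded-group records are skipped.  Records naming genes absent from
    the catalog follow ``unknown_gene``: ``"warn"`` drops them with a
    warning, ``"error"`` raises.  Samples are ordered by first appearance
    unless an explicit list is given.
    """
    catalog = variants or VariantCatalog()
    groups = catalog.group_labels
    if samples is None:
        ordered: list[str] = []
        for r in records:
            if r.sample_id not in ordered:
                ordered.append(r.sample_id)
        samples = ordered
    samples = list(samples)
    si = {s: i for i, s in enumerate(samples)}
    ri = {s: i for i, s in enumerate(groups)}
    counts = np.zeros((len(samples), len(genes), len(groups)), dtype=np.int64)
    n_unknown = 0
    for r in records:
        if r.excluded:
            continue
        if r.gene not in genes:
            if unknown_gene == "error":
                raise KeyError(f"gene {r.gene!r} not in gene catalog")
            n_unknown += 1
            continue
        if r.sample_id not in si:
            raise KeyError(f"sample {r.sample_id!r} not in declared sample list")
        counts[si[r.sample_id], genes.index_of(r.gene), ri[r.group]] += 1
    if n_unknown:
        warnings.warn(f"dropped {n_unknown} records naming genes absent from the "
                      "gene catalog", stacklevel=2)
    return CountTensor(tuple(samples), genes.genes, groups, counts)


def biomarker_values(tensor: CountTensor, spec: BiomarkerSpec) -> np.ndarray:
    """Per-sample biomarker values: sum counts over all genes and S-bar."""
    idx = [tensor.group_index(s) for s in spec.target_groups]
    return tensor.counts[:, :, idx].sum(axis=(1, 2)).astype(float)


def split_samples(
    samples: Sequence[str],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[str], list[str], list[str]]:
    """Randomly partition samples into train/validation/test sets.

    Sizes follow largest-remainder rounding with ties resolved toward the
    earlier split (train first), so 1144 samples at fractions
    (800, 171, 173)/1144 give exactly 800/171/173.  The partition is
    exhaustive, disjoint, and reproducible for a fixed seed.
    """
    fracs = np.asarray(fractions, dtype=float)
    if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    n = len(samples)
    if n < np.count_nonzero(fracs):
        raise ValueError("fewer samples than requested non-empty splits")
    raw = fracs * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    # distribute leftover units by largest fractional part, train-first ties
    order = np.lexsort((np.arange(3), -(raw - sizes)))
    for k in order[:remainder]:
        sizes[k] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [samples[i] for i in perm]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0]: sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return list(train), list(val), list(test)
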