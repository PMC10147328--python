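"""Reading, writing and harmonising the pipeline's external tables.

All on-disk formats are plain text: featureCounts-style TSV for counts,
GFF3 or BED6 for gene annotation, a two-column TSV for the 1:1 ortholog
map and a CSV sample sheet.  In memory everything is a pandas object
wrapped thinly enough that the rest of the package can stay vectorised.

Conventions
-----------
* Genomic coordinates are 1-based inclusive internally; BED input is
  converted on read and segment BED output is converted back on write.
* The canonical ortholog identifier is the species-N gene ID (the HIL
  background genome), so every downstream table is keyed by it.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CountMatrix",
    "OrthologMap",
    "HilexError",
    "CountFormatError",
    "OrthologMapError",
    "AnnotationError",
    "SampleSheetError",
    "read_counts",
    "write_counts",
    "read_orthologs",
    "restrict_to_orthologs",
    "filter_detectable",
    "read_annotation",
    "read_sample_sheet",
    "PARENT_B",
    "PARENT_N",
]

#: group label of the C. briggsae-like parent in sample sheets
PARENT_B = "species_B"
#: group label of the C. nigoni-like parent (the HIL background genome)
PARENT_N = "species_N"

#: featureCounts annotation columns that are skipped when present
_FEATURECOUNTS_ANNOT = {"Chr", "Start", "End", "Strand", "Length"}


class HilexError(Exception):
    """Base class for all typed failures raised by this package."""


class CountFormatError(HilexError):
    """A count table violated the format contract (non-integer cell,
    duplicated gene ID, missing file...)."""


class OrthologMapError(HilexError):
    """The 1:1 ortholog map violated one-to-one-ness or had no overlap."""


class AnnotationError(HilexError):
    """Gene annotation could not be parsed or is internally inconsistent."""


class SampleSheetError(HilexError):
    """Sample sheet missing columns, duplicated IDs or under-replicated."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a reference-genome tag.

    Parameters
    ----------
    counts
        DataFrame with gene IDs as index, sample IDs as columns and
        non-negative integer counts as values.
    reference_tag
        Which reference genome the reads were counted against:
        ``"refB"``, ``"refN"`` or ``"merged"``.
    """

    counts: pd.DataFrame
    reference_tag: str = "refN"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise CountFormatError(f"duplicated gene ID {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise CountFormatError("negative count encountered")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)], self.reference_tag)


@dataclass
class OrthologMap:
    """Strict 1:1 gene pairing between the two reference annotations."""

    pairs: pd.DataFrame = field(repr=False)  # columns gene_id_refB, gene_id_refN

    def __post_init__(self) -> None:
        for col in ("gene_id_refB", "gene_id_refN"):
            if col not in self.pairs.columns:
                raise OrthologMapError(f"ortholog map missing column {col!r}")
            if self.pairs[col].duplicated().any():
                dup = self.pairs[col][self.pairs[col].duplicated()].iloc[0]
                raise OrthologMapError(
                    f"gene ID {dup!r} appears in more than one ortholog pair"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def ids_for(self, reference_tag: str) -> pd.Series:
        """Gene IDs of one reference, indexed by the canonical (refN) ID."""
        col = "gene_id_refB" if reference_tag == "refB" else "gene_id_refN"
        return pd.Series(
            self.pairs[col].to_numpy(), index=self.pairs["gene_id_refN"].to_numpy()
        )


def read_counts(path, reference_tag: str = "refN") -> CountMatrix:
    """Read a featureCounts-style TSV into a :class:`CountMatrix`.

    The first non-``#`` line is the header; the first column is the gene
    ID and any ``Chr``/``Start``/``End``/``Strand``/``Length`` annotation
    columns are dropped.  Input gene order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise CountFormatError(f"count file not found: {path}")
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if table.shape[1] < 2:
        raise CountFormatError(f"{path}: need a gene-ID column plus >=1 sample column")
    gene_col = table.columns[0]
    sample_cols = [c for c in table.columns[1:] if c not in _FEATURECOUNTS_ANNOT]
    if not sample_cols:
        raise CountFormatError(f"{path}: no sample columns after annotation columns")
    counts = table[sample_cols].copy()
    for col in sample_cols:
        numeric = pd.to_numeric(counts[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(bad.idxmax())
            raise CountFormatError(
                f"{path}: non-integer count {table.loc[row, col]!r} at "
                f"gene {table.loc[row, gene_col]!r}, column {col!r}"
            )
        counts[col] = numeric.astype("int64")
    counts.index = pd.Index(table[gene_col], name="gene_id")
    return CountMatrix(counts, reference_tag)


def write_counts(m: CountMatrix, path) -> None:
    """Write a count matrix as TSV (gene_id first column)."""
    m.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_orthologs(path) -> OrthologMap:
    """Read the two-column ortholog TSV (header gene_id_refB, gene_id_refN)."""
    path = Path(path)
    if not path.exists():
        raise OrthologMapError(f"ortholog map not found: {path}")
    return OrthologMap(pd.read_csv(path, sep="\t", dtype=str))


def restrict_to_orthologs(m: CountMatrix, orthologs: OrthologMap) -> CountMatrix:
    """Keep only 1:1 orthologs and re-key the matrix to canonical IDs.

    The matrix's ``reference_tag`` selects which ortholog-map column is
    matched; the output is indexed by the canonical (refN) ID and sorted
    by it, so matrices from both references align row-for-row.
    """
    ids = orthologs.ids_for(m.reference_tag)  # canonical -> tag-specific ID
    present = ids[ids.isin(m.gene_ids)]
    if present.empty:
        raise OrthologMapError(
            f"no overlap between the {m.reference_tag} count matrix and the ortholog map"
        )
    present = present.sort_index()
    counts = m.counts.loc[present.to_numpy()].copy()
    counts.index = pd.Index(present.index, name="gene_id")
    return CountMatrix(counts, m.reference_tag)


def filter_detectable(m: CountMatrix, min_mean: float = 1.0) -> CountMatrix:
    """Detectable-expression filter.

    A gene is retained when its mean raw count across all samples is at
    least ``min_mean`` and at least one sample has a nonzero count.
    Idempotent by construction.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    means = m.counts.mean(axis=1)
    keep = (means >= min_mean) & (m.counts.sum(axis=1) > 0)
    return CountMatrix(m.counts.loc[keep], m.reference_tag)


def _chrom_class(chrom: str, x_chroms: frozenset) -> str:
    return "X" if chrom in x_chroms else "autosome"


_DEFAULT_X = frozenset({"X", "chrX", "ChrX"})


def read_annotation(path, x_chroms=_DEFAULT_X) -> pd.DataFrame:
    """Read gene annotation from GFF3 or BED6 into a coordinate table.

    Returns a DataFrame indexed by gene_id with columns ``chrom``,
    ``start``, ``end`` (1-based inclusive), ``strand`` and
    ``chrom_class`` ("autosome" or "X" per the *x_chroms* set).
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str, "gene_id": str, "strand": str},
        )
        out = pd.DataFrame(
            {
                "chrom": bed["chrom"].to_numpy(),
                "start": bed["start"].to_numpy(dtype=int) + 1,  # BED is 0-based half-open
                "end": bed["end"].to_numpy(dtype=int),
                "strand": bed["strand"].fillna(".").to_numpy(),
            },
            index=pd.Index(bed["gene_id"].to_numpy(), name="gene_id"),
        )
    else:
        out = _read_gff3_genes(path)
    if (out["start"] > out["end"]).any():
        bad = out.index[out["start"] > out["end"]][0]
        raise AnnotationError(f"gene {bad!r} has start > end")
    if out.index.has_duplicates:
        dup = out.index[out.index.duplicated()][0]
        raise AnnotationError(f"duplicated gene ID {dup!r} in annotation")
    out["chrom_class"] = [_chrom_class(c, frozenset(x_chroms)) for c in out["chrom"]]
    return out


def _read_gff3_genes(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        from_string=False,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand or "."))
    if not rows:
        raise AnnotationError(f"{path}: no gene features found")
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return frame.set_index("gene_id")


def read_sample_sheet(path, min_replicates: int = 2) -> pd.DataFrame:
    """Read the sample sheet CSV (sample_id, group, replicate).

    Groups are the two parental labels plus one label per HIL.  Each
    group must have at least *min_replicates* members (the study design
    uses triplicates).
    """
    path = Path(path)
    if not path.exists():
        raise SampleSheetError(f"sample sheet not found: {path}")
    sheet = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group", "replicate"):
        if col not in sheet.columns:
            raise SampleSheetError(f"sample sheet missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise SampleSheetError(f"duplicated sample ID {dup!r}")
    small = sheet.groupby("group").size()
    under = small[small < min_replicates]
    if not under.empty:
        raise SampleSheetError(
            f"group {under.index[0]!r} has {int(under.iloc[0])} replicate(s); "
            f"need >= {min_replicates}"
        )
    return sheet.set_index("sample_id")


def hil_groups(samples: pd.DataFrame) -> list[str]:
    """The non-parental group labels, in sheet order."""
    seen: list[str] = []
    for g in samples["group"]:
        if g not in (PARENT_B, PARENT_N) and g not in seen:
            seen.append(g)
    return seen


def samples_in_group(samples: pd.DataFrame, group: str) -> list[str]:
    return list(samples.index[samples["group"] == group])
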