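"""Domain types for the biomarker screen, plus readers/writers for the
TSV/BED dialects the pipeline exchanges.

The screen's atomic unit is the *bioset*: a statistically filtered list of
differentially expressed genes with signed fold-changes from one
experimental comparison.  A *biomarker* is a fixed signed probe/gene set
with average fold-changes that serves as the query signature.  Fold-changes
follow the microarray signed-ratio convention: values >= 1 mean
up-regulation and down-regulation is stored as -(control/treated), so
|fold_change| >= 1 always.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

SEXES = frozenset({"male", "female", "mixed", "unknown"})
FACTOR_TYPES = frozenset({"chemical", "genetic", "diet", "hormone", "control", "other"})

#: Fold-change floor applied when biosets are imported (signed-ratio scale).
DEFAULT_FC_THRESHOLD = 1.2

#: Minimum |average fold-change| for a biomarker entry.
BIOMARKER_MIN_FC = 1.5


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect or a type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Annotation:
    """Experimental metadata attached to a bioset.

    ``factor_type`` is restricted to a closed vocabulary so that grouped
    summaries over the compendium are well defined.  ``maturity`` records
    whether the animals were sexually mature (sex-comparisons are only
    meaningful in mature animals) and defaults to True.
    """

    accession: str | None = None
    tissue: str = "liver"
    sex: str = "unknown"
    factor_type: str = "other"
    factor_name: str = ""
    duration: str = ""
    dose: str = ""
    route: str = ""
    maturity: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {sorted(SEXES)}")
        if self.factor_type not in FACTOR_TYPES:
            raise ValueError(
                f"unknown factor_type {self.factor_type!r}; expected one of {sorted(FACTOR_TYPES)}"
            )

    FIELDS = (
        "accession", "tissue", "sex", "factor_type", "factor_name",
        "duration", "dose", "route", "maturity",
    )


@dataclass(frozen=True)
class BiosetEntry:
    gene_id: str
    fold_change: float
    adj_p: float | None = None


@dataclass(frozen=True)
class Bioset:
    """A statistically filtered gene list with signed fold-changes."""

    bioset_id: str
    entries: tuple[BiosetEntry, ...]
    annotations: Annotation = field(default_factory=Annotation)
    fc_threshold: float = DEFAULT_FC_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError(f"bioset {self.bioset_id!r}: no entries")
        seen: set[str] = set()
        for e in self.entries:
            if e.gene_id in seen:
                raise ValueError(f"bioset {self.bioset_id!r}: duplicate gene {e.gene_id!r}")
            seen.add(e.gene_id)
            if not math.isfinite(e.fold_change) or e.fold_change == 0:
                raise ValueError(
                    f"bioset {self.bioset_id!r}: non-finite/zero fold-change for {e.gene_id!r}"
                )
            if abs(e.fold_change) < self.fc_threshold:
                raise ValueError(
                    f"bioset {self.bioset_id!r}: |fold-change| {abs(e.fold_change):g} for "
                    f"{e.gene_id!r} is below the threshold {self.fc_threshold:g}"
                )
            if e.adj_p is not None and not (0.0 <= e.adj_p <= 1.0):
                raise ValueError(f"bioset {self.bioset_id!r}: adj_p out of [0,1] for {e.gene_id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_signs(self) -> dict[str, int]:
        """Map gene_id -> +1/-1 sign of its fold-change."""
        return {e.gene_id: (1 if e.fold_change > 0 else -1) for e in self.entries}

    @property
    def gene_fold_changes(self) -> dict[str, float]:
        return {e.gene_id: e.fold_change for e in self.entries}


@dataclass(frozen=True)
class BiomarkerEntry:
    probe_id: str
    gene_id: str
    avg_fold_change: float


@dataclass(frozen=True)
class Biomarker:
    """A fixed signed probe/gene set used as the query signature.

    Invariants: probe ids unique, every |avg_fold_change| >= 1.5, and all
    probes of one gene share a direction, so the up- and down-regulated
    gene sets partition the biomarker.
    """

    name: str
    entries: tuple[BiomarkerEntry, ...]
    derived_from: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError(f"biomarker {self.name!r}: no entries")
        probes: set[str] = set()
        gene_sign: dict[str, int] = {}
        for e in self.entries:
            if e.probe_id in probes:
                raise ValueError(f"biomarker {self.name!r}: duplicate probe {e.probe_id!r}")
            probes.add(e.probe_id)
            if abs(e.avg_fold_change) < BIOMARKER_MIN_FC:
                raise ValueError(
                    f"biomarker {self.name!r}: |avg fold-change| {abs(e.avg_fold_change):g} "
                    f"for probe {e.probe_id!r} is below {BIOMARKER_MIN_FC}"
                )
            s = 1 if e.avg_fold_change > 0 else -1
            if gene_sign.setdefault(e.gene_id, s) != s:
                raise ValueError(
                    f"biomarker {self.name!r}: gene {e.gene_id!r} has probes of opposite sign"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries if e.avg_fold_change > 0)

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries if e.avg_fold_change < 0)

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def flipped(self) -> "Biomarker":
        """Return the sign-mirrored biomarker (every avg fold-change negated)."""
        return Biomarker(
            name=f"{self.name}-flipped",
            entries=tuple(
                BiomarkerEntry(e.probe_id, e.gene_id, -e.avg_fold_change) for e in self.entries
            ),
            derived_from=self.derived_from,
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of linear-scale intensities with group labels."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: "object"  # numpy array, genes x samples
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        import numpy as np

        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {v.shape} does not match {len(self.gene_ids)} genes x "
                f"{len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        counts: dict[str, int] = {}
        for s in self.sample_ids:
            counts[self.groups[s]] = counts.get(self.groups[s], 0) + 1
        small = [g for g, n in counts.items() if n < 2]
        if small:
            raise ValueError(f"groups with < 2 samples: {small}")

    def group_columns(self, group: str) -> list[int]:
        cols = [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]
        if not cols:
            raise ValueError(f"unknown group label {group!r}")
        return cols


@dataclass(frozen=True)
class RunningFisherResult:
    """Outcome of one biomarker-vs-bioset comparison.

    ``signed_score`` is direction x -log10(p_value): positive means the
    bioset is correlated with the biomarker (activation-like), negative
    means anti-correlated (suppression-like).
    """

    direction: int
    p_value: float
    signed_score: float
    overlap_concordant: int
    overlap_discordant: int
    per_pair_p: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


@dataclass(frozen=True)
class BiomarkerCall:
    signed_score: float
    p_value: float
    call: str  # activated | suppressed | no-call

    def __post_init__(self) -> None:
        if self.call not in ("activated", "suppressed", "no-call"):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class ScreenRecord:
    """One compendium master-table row: bioset annotations plus per-biomarker calls."""

    bioset_id: str
    annotation: Annotation
    calls: Mapping[str, BiomarkerCall]  # biomarker name -> call


@dataclass(frozen=True)
class Peak:
    """A 0-based half-open genomic interval; the summit is its midpoint."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")

    @property
    def summit(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    genes: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_ids in annotation")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_bioset(
    path: str | Path,
    threshold: float = DEFAULT_FC_THRESHOLD,
    bioset_id: str | None = None,
    annotations: Annotation | None = None,
) -> Bioset:
    """Read a bioset TSV (columns gene_id, fold_change, optional adj_p).

    Rows with |fold_change| < ``threshold`` are dropped (the count is
    logged); the result must still satisfy all Bioset invariants.
    """
    path = Path(path)
    df = _read_tsv(path, ["gene_id", "fold_change"])
    if len(df) == 0:
        raise FormatError(f"{path}: no entries")
    entries: list[BiosetEntry] = []
    seen: set[str] = set()
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        gene = str(row.gene_id)
        try:
            fc = float(row.fold_change)
        except (TypeError, ValueError):
            raise FormatError(f"{path}, line {i}: non-numeric fold-change {row.fold_change!r}")
        if gene in seen:
            raise FormatError(f"{path}, line {i}: duplicate gene {gene!r}")
        seen.add(gene)
        if abs(fc) < threshold:
            dropped += 1
            continue
        adj_p: float | None = None
        if "adj_p" in df.columns:
            raw = getattr(row, "adj_p")
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) and str(raw) != "":
                adj_p = float(raw)
        entries.append(BiosetEntry(gene, fc, adj_p))
    if dropped:
        log.info("%s: dropped %d rows below |FC| threshold %g", path, dropped, threshold)
    if not entries:
        raise FormatError(f"{path}: no entries pass the |FC| >= {threshold:g} filter")
    return Bioset(
        bioset_id=bioset_id or path.stem,
        entries=tuple(entries),
        annotations=annotations or Annotation(),
        fc_threshold=threshold,
    )


def write_bioset(bioset: Bioset, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in bioset.entries],
            "fold_change": [e.fold_change for e in bioset.entries],
            "adj_p": [e.adj_p if e.adj_p is not None else "" for e in bioset.entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_biomarker(path: str | Path, name: str | None = None) -> Biomarker:
    """Read a biomarker TSV (columns probe_id, gene_id, avg_fold_change)."""
    path = Path(path)
    df = _read_tsv(path, ["probe_id", "gene_id", "avg_fold_change"])
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            fc = float(row.avg_fold_change)
        except (TypeError, ValueError):
            raise FormatError(f"{path}, line {i}: non-numeric avg_fold_change")
        entries.append(BiomarkerEntry(str(row.probe_id), str(row.gene_id), fc))
    return Biomarker(name=name or path.stem, entries=tuple(entries))


def write_biomarker(biomarker: Biomarker, path: str | Path) -> None:
    pd.DataFrame(
        {
            "probe_id": [e.probe_id for e in biomarker.entries],
            "gene_id": [e.gene_id for e in biomarker.entries],
            "avg_fold_change": [e.avg_fold_change for e in biomarker.entries],
        }
    ).to_csv(path, sep="\t", index=False)


def write_screen_table(records: Sequence[ScreenRecord], path: str | Path) -> None:
    """Write the master table: one row per bioset, annotation columns, then
    signed score / p-value / call per biomarker.  Round-trips losslessly
    through :func:`read_screen_table`."""
    if not records:
        raise ValueError("no records to write")
    names = list(records[0].calls.keys())
    rows = []
    for r in records:
        row: dict[str, object] = {"bioset_id": r.bioset_id}
        for f in Annotation.FIELDS:
            v = getattr(r.annotation, f)
            row[f] = "" if v is None else v
        for n in names:
            c = r.calls[n]
            row[f"{n}_signed_score"] = repr(c.signed_score)
            row[f"{n}_p_value"] = repr(c.p_value)
            row[f"{n}_call"] = c.call
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_screen_table(path: str | Path) -> list[ScreenRecord]:
    df = _read_tsv(Path(path), ["bioset_id"])
    names = sorted(
        {c[: -len("_signed_score")] for c in df.columns if c.endswith("_signed_score")}
    )
    records = []
    for row in df.to_dict("records"):
        ann = Annotation(
            accession=(row["accession"] if isinstance(row["accession"], str) and row["accession"] else None),
            tissue=str(row["tissue"]),
            sex=str(row["sex"]),
            factor_type=str(row["factor_type"]),
            factor_name=str(row["factor_name"]) if isinstance(row["factor_name"], str) else "",
            duration=str(row["duration"]) if isinstance(row["duration"], str) else "",
            dose=str(row["dose"]) if isinstance(row["dose"], str) else "",
            route=str(row["route"]) if isinstance(row["route"], str) else "",
            maturity=str(row["maturity"]) == "True",
        )
        calls = {
            n: BiomarkerCall(
                signed_score=float(row[f"{n}_signed_score"]),
                p_value=float(row[f"{n}_p_value"]),
                call=str(row[f"{n}_call"]),
            )
            for n in names
        }
        records.append(ScreenRecord(str(row["bioset_id"]), ann, calls))
    return records


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ peak file; intervals are 0-based half-open."""
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}, line {i}: expected >= 3 BED fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}, line {i}: non-integer coordinates")
            if start >= end:
                raise FormatError(f"{path}, line {i}: start >= end")
            peaks.append(Peak(fields[0], start, end))
    return PeakSet(tuple(peaks))


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a 5-column gene annotation TSV (gene_id, chrom, start, end, strand).

    TSS = start for '+'-strand genes and end - 1 for '-'-strand genes
    (0-based half-open convention).
    """
    path = Path(path)
    df = _read_tsv(path, ["gene_id", "chrom", "start", "end", "strand"])
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise FormatError(f"{path}, line {i}: non-integer coordinates")
        if start >= end:
            raise FormatError(f"{path}, line {i}: start >= end")
        strand = str(row.strand)
        if strand not in ("+", "-"):
            raise FormatError(f"{path}, line {i}: unknown strand {strand!r}")
        tss = start if strand == "+" else end - 1
        genes.append(GeneRecord(str(row.gene_id), str(row.chrom), tss, strand))
    return GeneAnnotation(tuple(genes))


def write_gene_annotation(
    genes: Iterable[tuple[str, str, int, int, str]], path: str | Path
) -> None:
    """Write (gene_id, chrom, start, end, strand) tuples as the 5-column TSV."""
    pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_matrix(matrix_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene_id) plus a sample sheet
    with columns sample_id and group."""
    import numpy as np

    m = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = _read_tsv(samples_path, ["sample_id", "group"])
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"].astype(str)))
    return ExpressionMatrix(
        gene_ids=tuple(str(g) for g in m.index),
        sample_ids=tuple(str(s) for s in m.columns),
        values=np.asarray(m.values, dtype=float),
        groups=groups,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, matrix_path: str | Path, samples_path: str | Path
) -> None:
    pd.DataFrame(matrix.values, index=list(matrix.gene_ids), columns=list(matrix.sample_ids)).to_csv(
        matrix_path, sep="\t", index_label="gene_id"
    )
    pd.DataFrame(
        {"sample_id": list(matrix.sample_ids), "group": [matrix.groups[s] for s in matrix.sample_ids]}
    ).to_csv(samples_path, sep="\t", index=False)
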