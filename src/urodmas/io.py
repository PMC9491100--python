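"""Readers and writers for every external representation the pipeline touches.

Formats: BED3/BED4 capture panel, 7-column genome-wide cytosine report
(methylation-extractor layout), TSV sample sheet, TSV sample x window
matrices, TSV score tables, BED6 gene models and a versioned JSON document
for trained pattern models.  All readers validate; all writers round-trip
(exactly for integers, to 12 significant digits for reals).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    COHORTS,
    CONTEXTS,
    CaptureRegion,
    CountMatrix,
    CytosineRecord,
    DMASMatrix,
    GeneRecord,
    OrderingPattern,
    ParseError,
    PatternModel,
    SampleSheetEntry,
    TupleFeature,
    ValidationError,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

SHEET_COLUMNS = [
    "sample_id",
    "cohort",
    "patient_id",
    "timepoint",
    "age",
    "sex",
    "smoking",
    "stage",
    "grade",
]


# ---------------------------------------------------------------------------
# capture panel (BED)
# ---------------------------------------------------------------------------

def read_capture_bed(path) -> list[CaptureRegion]:
    """Read a BED3/BED4 capture panel into sorted, validated regions.

    The optional 4th column is the region id; absent, ids are synthesized
    as ``chrom:start-end``.  Overlapping regions on one chromosome are an
    error: window identity downstream must be unambiguous.
    """
    path = Path(path)
    regions: list[CaptureRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated columns, got {len(fields)}",
                    path,
                    lineno,
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from exc
            region_id = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            try:
                regions.append(CaptureRegion(chrom, start, end, region_id))
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    if not regions:
        logger.warning("capture panel %s is empty", path)
        return []
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate region ids in {path}: {dupes[:5]}")
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValidationError(
                f"overlapping capture regions {a.region_id} and {b.region_id} on {a.chrom}"
            )
    return regions


def write_capture_bed(path, regions: Iterable[CaptureRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# cytosine report
# ---------------------------------------------------------------------------

def read_cytosine_report(
    path, contexts: Optional[Sequence[str]] = None
) -> Iterator[CytosineRecord]:
    """Stream a 7-column genome-wide cytosine report.

    Columns: chrom, 1-based position, strand, count methylated, count
    unmethylated, context, trinucleotide (ignored).  Only records whose
    context is in ``contexts`` are yielded; the default keeps all three
    contexts (CpG, CHG, CHH) on both strands.
    """
    keep = frozenset(CONTEXTS if contexts is None else contexts)
    unknown = keep - set(CONTEXTS)
    if unknown:
        raise ValidationError(f"unknown contexts requested: {sorted(unknown)}")
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"expected >=6 tab-separated columns, got {len(fields)}", path, lineno
                )
            chrom, pos_s, strand, n_meth_s, n_unmeth_s, context = fields[:6]
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(n_meth_s), int(n_unmeth_s)
            except ValueError as exc:
                raise ParseError(f"non-integer field: {exc}", path, lineno) from exc
            if context not in CONTEXTS:
                raise ParseError(f"unknown context {context!r}", path, lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"bad strand {strand!r}", path, lineno)
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                raise ParseError("negative count or non-positive position", path, lineno)
            if context in keep:
                yield CytosineRecord(chrom, pos, strand, n_meth, n_unmeth, context)


def read_cytosine_report_frame(
    path, contexts: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Vectorized cytosine-report reader (same validation, columnar result)."""
    keep = frozenset(CONTEXTS if contexts is None else contexts)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"],
        usecols=range(6),
        dtype={"chrom": str, "strand": str, "context": str},
    )
    for col in ("pos", "n_meth", "n_unmeth"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ParseError(f"non-integer values in column {col}", path)
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ParseError(
            f"unknown context {df.loc[bad, 'context'].iloc[0]!r}",
            path,
            int(bad.idxmax()) + 1,
        )
    return df[df["context"].isin(keep)].reset_index(drop=True)


def write_cytosine_report(path, records: Iterable[CytosineRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            tri = "CGA" if r.context == "CpG" else ("CAG" if r.context == "CHG" else "CTT")
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.n_meth}\t{r.n_unmeth}\t{r.context}\t{tri}\n"
            )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleSheetEntry]:
    """Read the TSV sample sheet; cohort labels are case-folded to the closed set."""
    df = pd.read_csv(path, sep="\t", dtype=str).replace({np.nan: None})
    if "sample_id" not in df.columns or "cohort" not in df.columns:
        raise ParseError("sample sheet needs at least sample_id and cohort columns", path)
    entries = []
    for _, row in df.iterrows():
        cohort = (row["cohort"] or "").strip().lower().replace("-", "_").replace(" ", "_")
        if cohort != row["cohort"]:
            logger.warning(
                "sample %s: cohort label %r normalized to %r",
                row["sample_id"],
                row["cohort"],
                cohort,
            )
        if cohort not in COHORTS:
            raise ValidationError(
                f"sample {row['sample_id']}: unknown cohort {row['cohort']!r}"
            )
        tp = row.get("timepoint")
        entries.append(
            SampleSheetEntry(
                sample_id=row["sample_id"],
                cohort=cohort,
                patient_id=row.get("patient_id"),
                timepoint=int(tp) if tp not in (None, "") else None,
                age=float(row["age"]) if row.get("age") not in (None, "") else None,
                sex=row.get("sex"),
                smoking=row.get("smoking"),
                stage=row.get("stage"),
                grade=row.get("grade"),
            )
        )
    ids = [e.sample_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id in sheet: {dupes[:5]}")
    return entries


def write_sample_sheet(path, entries: Iterable[SampleSheetEntry]) -> None:
    rows = [
        {
            c: getattr(e, c) if getattr(e, c) is not None else ""
            for c in SHEET_COLUMNS
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def sheet_to_frame(entries: Iterable[SampleSheetEntry]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(e, c) for c in SHEET_COLUMNS} for e in entries])


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(path, sample_ids: Sequence[str], window_ids: Sequence[str], values: np.ndarray) -> None:
    """Write a samples x windows matrix as TSV, window ids as header."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(window_ids) + "\n")
        integral = np.issubdtype(values.dtype, np.integer)
        for sid, row in zip(sample_ids, values):
            if integral:
                cells = [str(int(v)) for v in row]
            else:
                # repr is the shortest exact round-trip representation
                cells = [repr(float(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_matrix(path, dtype=float) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=dtype)


def write_counts(path_methyl, path_unmethyl, counts: CountMatrix) -> None:
    write_matrix(path_methyl, counts.sample_ids, counts.window_ids, counts.methyl)
    write_matrix(path_unmethyl, counts.sample_ids, counts.window_ids, counts.unmethyl)


def read_counts(path_methyl, path_unmethyl) -> CountMatrix:
    s1, w1, m = read_matrix(path_methyl, dtype=np.int64)
    s2, w2, u = read_matrix(path_unmethyl, dtype=np.int64)
    if s1 != s2 or w1 != w2:
        raise ValidationError("methyl and unmethyl matrices have mismatched axes")
    return CountMatrix(s1, w1, m, u)


def write_dmas(path, dmas: DMASMatrix) -> None:
    write_matrix(path, dmas.sample_ids, dmas.window_ids, dmas.values)


def read_dmas(path) -> DMASMatrix:
    s, w, v = read_matrix(path, dtype=float)
    return DMASMatrix(s, w, v)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["sample_id", "h_score", "c_score", "d_score", "z"]


def write_scores(path, scores: pd.DataFrame) -> None:
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValidationError(f"score table missing columns {missing}")
    out = scores[SCORE_COLUMNS].copy()
    for c in SCORE_COLUMNS[1:]:
        out[c] = out[c].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"score table missing columns {missing}")
    return df[SCORE_COLUMNS]


# ---------------------------------------------------------------------------
# model serialization (versioned JSON)
# ---------------------------------------------------------------------------

def _pattern_to_dict(p: OrderingPattern) -> dict:
    return {
        "region_id": p.feature.region_id,
        "window_ids": list(p.feature.window_ids),
        "start_index": p.feature.start_index,
        "permutation": list(p.permutation),
        "class_label": p.class_label,
        "weight": p.weight,
        "freq_healthy": p.freq_healthy,
        "freq_cancer": p.freq_cancer,
    }


def _pattern_from_dict(d: dict) -> OrderingPattern:
    return OrderingPattern(
        feature=TupleFeature(d["region_id"], tuple(d["window_ids"]), d["start_index"]),
        permutation=tuple(d["permutation"]),
        class_label=d["class_label"],
        weight=d["weight"],
        freq_healthy=d["freq_healthy"],
        freq_cancer=d["freq_cancer"],
    )


def save_model(path, model: PatternModel) -> None:
    """Serialize a pattern model to versioned JSON (deterministic bytes)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": model.k,
        "delta_min": model.delta_min,
        "max_patterns_per_class": model.max_patterns_per_class,
        "metadata": model.metadata,
        "healthy_patterns": [_pattern_to_dict(p) for p in model.healthy_patterns],
        "cancer_patterns": [_pattern_to_dict(p) for p in model.cancer_patterns],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path) -> PatternModel:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format_version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    return PatternModel(
        k=doc["k"],
        delta_min=doc["delta_min"],
        max_patterns_per_class=doc["max_patterns_per_class"],
        healthy_patterns=[_pattern_from_dict(d) for d in doc["healthy_patterns"]],
        cancer_patterns=[_pattern_from_dict(d) for d in doc["cancer_patterns"]],
        metadata=doc.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# window catalog
# ---------------------------------------------------------------------------

def write_catalog(path, catalog) -> None:
    with open(path, "w") as fh:
        fh.write(f"#window_length={catalog.window_length}\n")
        fh.write("window_id\tregion_id\tchrom\tstart\tend\tindex_in_region\n")
        for w in catalog:
            fh.write(
                f"{w.window_id}\t{w.region_id}\t{w.chrom}\t{w.start}\t{w.end}\t{w.index_in_region}\n"
            )


def read_catalog(path):
    from .types import WindowCatalog  # local to avoid cycle confusion

    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#window_length="):
            raise ParseError("missing #window_length header", path, 1)
        window_length = int(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", dtype={"window_id": str, "region_id": str, "chrom": str})
    from .types import Window

    windows = [
        Window(r.window_id, r.region_id, r.chrom, int(r.start), int(r.end), int(r.index_in_region))
        for r in df.itertuples()
    ]
    return WindowCatalog(windows, window_length)


# ---------------------------------------------------------------------------
# gene models (BED6)
# ---------------------------------------------------------------------------

def read_genes_bed(path) -> list[GeneRecord]:
    """Read gene intervals from BED4/BED6 (name column = gene id)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("gene BED needs >=4 columns (chrom, start, end, name)", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from exc
            strand = fields[5] if len(fields) >= 6 else "+"
            genes.append(GeneRecord(fields[3], fields[0], start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes
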