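"""Readers and writers: delimited count/taxonomy/metadata tables, BIOM,
PathoScope-style per-sample reports, and the zip session archive.

BIOM v1 (JSON, dense or sparse) is read and written directly — output is
always v1 sparse for interoperability; BIOM v2 (HDF5) is read-only and only
when ``h5py`` is importable. The session archive is a zip container holding
the three member TSVs plus a JSON manifest (format version, rank list,
provenance log), chosen over a binary pickle for cross-language portability.
"""

from __future__ import annotations

import json
import re
import warnings
import zipfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    RANKS,
    UNCLASSIFIED,
    MicrobiomeExperiment,
    TaxonomyTable,
    create_experiment,
)
from .errors import ParseError, ValidationError, VersionError

ARCHIVE_FORMAT_VERSION = "1.0"

#: Greengenes-style lineage prefixes mapped onto canonical ranks.
GREENGENES_PREFIXES = {
    "k": "superkingdom",
    "d": "superkingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

PATHOSCOPE_ID_COLUMN = "Genome"
PATHOSCOPE_COUNT_COLUMN = "Final Best Hit Read Numbers"
TAXID_PATTERN = re.compile(r"ti\|(\d+)")


# ---------------------------------------------------------------------------
# delimited tables

def _parse_count_cell(raw: str, path: str, line: int) -> int:
    try:
        value = float(raw)
    except ValueError:
        raise ParseError(f"non-numeric count {raw!r}", path, line) from None
    rounded = round(value)
    if abs(value - rounded) > 1e-9 or value < 0:
        raise ParseError(f"count must be a non-negative integer, got {raw!r}",
                         path, line)
    return int(rounded)


def read_count_table(
    path,
    orientation: str = "features_in_rows",
    delimiter: str = "\t",
) -> pd.DataFrame:
    """Read a labelled count matrix, normalized to features x samples.

    The file must be rectangular with a header row and a leading row-label
    column; float cells integral to within 1e-9 (e.g. ``"5.0"``) are accepted
    and cast.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = str(path)
    rows = []
    labels = []
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError("empty file or blank header", path, 1)
        header = header_line.rstrip("\n").split(delimiter)
        columns = [c.strip() for c in header[1:]]
        if not columns:
            raise ParseError("header has no data columns", path, 1)
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(delimiter)
            if len(cells) != width:
                raise ParseError(
                    f"ragged row: expected {width} cells, found {len(cells)}",
                    path, lineno,
                )
            labels.append(cells[0].strip())
            rows.append([_parse_count_cell(c, path, lineno) for c in cells[1:]])
    if not rows:
        raise ParseError("no data rows", path, 2)
    frame = pd.DataFrame(rows, index=labels, columns=columns, dtype=np.int64)
    if frame.index.duplicated().any():
        dupe = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"duplicate row label {dupe!r}", path)
    if frame.columns.duplicated().any():
        dupe = frame.columns[frame.columns.duplicated()][0]
        raise ParseError(f"duplicate column label {dupe!r}", path)
    if orientation == "samples_in_rows":
        frame = frame.T
    return frame


def read_taxonomy_table(path, delimiter: str = "\t") -> TaxonomyTable:
    """Read a per-feature lineage table; headers are matched to canonical
    ranks case-insensitively and blanks become the explicit missing marker."""
    path = str(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse taxonomy table: {exc}", path) from exc
    frame.index = frame.index.astype(str)
    try:
        return TaxonomyTable.from_frame(frame)
    except ValidationError as exc:
        raise ParseError(str(exc), path) from exc


def read_metadata_table(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a samples x covariates metadata table (TSV by default)."""
    path = str(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse metadata table: {exc}", path) from exc
    frame.index = frame.index.astype(str)
    return frame


# ---------------------------------------------------------------------------
# BIOM

def _parse_greengenes_lineage(entries) -> dict[str, str]:
    """Parse a BIOM taxonomy list into rank -> label, stripping g__ prefixes.

    Bare (unprefixed) labels are assigned to ranks positionally.
    """
    out: dict[str, str] = {}
    bare_rank = 0
    for raw in entries:
        label = str(raw).strip()
        if not label:
            continue
        m = re.match(r"^([a-zA-Z])__(.*)$", label)
        if m:
            prefix, name = m.group(1).lower(), m.group(2).strip()
            rank = GREENGENES_PREFIXES.get(prefix)
            if rank:
                out[rank] = name if name else UNCLASSIFIED
                bare_rank = RANKS.index(rank) + 1
            continue
        if bare_rank < len(RANKS):
            out[RANKS[bare_rank]] = label
            bare_rank += 1
    return out


def read_biom(path) -> MicrobiomeExperiment:
    """Read a BIOM file (v1 JSON dense/sparse; v2 HDF5 when h5py is present)."""
    path = str(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return _read_biom_v2(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed BIOM JSON: {exc}", path) from exc
    fmt = str(doc.get("format", ""))
    if "1.0" not in fmt and "Biological Observation Matrix" not in fmt:
        raise VersionError(f"unsupported BIOM format {fmt!r}", path)
    shape = doc.get("shape")
    n_obs, n_samp = int(shape[0]), int(shape[1])
    obs_ids = [str(r["id"]) for r in doc["rows"]]
    samp_ids = [str(c["id"]) for c in doc["columns"]]
    matrix = np.zeros((n_obs, n_samp))
    mtype = doc.get("matrix_type", "sparse")
    if mtype == "dense":
        matrix[:] = np.asarray(doc["data"], dtype=float)
    elif mtype == "sparse":
        for i, j, v in doc["data"]:
            matrix[int(i), int(j)] = float(v)
    else:
        raise ParseError(f"unknown matrix_type {mtype!r}", path)
    counts = pd.DataFrame(matrix, index=obs_ids, columns=samp_ids)

    tax_rows = {}
    for row in doc["rows"]:
        md = row.get("metadata") or {}
        lineage = md.get("taxonomy")
        if lineage:
            if isinstance(lineage, str):
                lineage = [s for s in re.split(r";\s*", lineage)]
            tax_rows[str(row["id"])] = _parse_greengenes_lineage(lineage)
    taxonomy = None
    if tax_rows:
        tframe = pd.DataFrame.from_dict(tax_rows, orient="index")
        tframe = tframe.reindex(obs_ids)
        taxonomy = TaxonomyTable.from_frame(tframe)

    meta_rows = {}
    for col in doc["columns"]:
        md = col.get("metadata") or {}
        meta_rows[str(col["id"])] = md
    metadata = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(samp_ids)
    return create_experiment(counts, taxonomy=taxonomy, metadata=metadata)


def _read_biom_v2(path: str) -> MicrobiomeExperiment:
    try:
        import h5py
    except ImportError as exc:
        raise VersionError(
            "BIOM v2 (HDF5) requires the optional h5py backend", path
        ) from exc
    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x)
                   for x in f["observation/ids"][...]]
        samp_ids = [x.decode() if isinstance(x, bytes) else str(x)
                    for x in f["sample/ids"][...]]
        data = f["observation/matrix/data"][...]
        indices = f["observation/matrix/indices"][...]
        indptr = f["observation/matrix/indptr"][...]
        matrix = np.zeros((len(obs_ids), len(samp_ids)))
        for i in range(len(obs_ids)):
            sl = slice(indptr[i], indptr[i + 1])
            matrix[i, indices[sl]] = data[sl]
        taxonomy = None
        if "observation/metadata/taxonomy" in f:
            tax_raw = f["observation/metadata/taxonomy"][...]
            rows = {}
            for oid, lineage in zip(obs_ids, tax_raw):
                entries = [x.decode() if isinstance(x, bytes) else str(x)
                           for x in np.atleast_1d(lineage)]
                rows[oid] = _parse_greengenes_lineage(entries)
            taxonomy = TaxonomyTable.from_frame(
                pd.DataFrame.from_dict(rows, orient="index").reindex(obs_ids)
            )
    counts = pd.DataFrame(matrix, index=obs_ids, columns=samp_ids)
    return create_experiment(counts, taxonomy=taxonomy,
                             metadata=pd.DataFrame(index=samp_ids))


def write_biom(exp: MicrobiomeExperiment, path) -> None:
    """Write a BIOM v1 JSON file (sparse encoding)."""
    path = str(path)
    mat = exp.counts.to_numpy()
    data = [
        [int(i), int(j), int(mat[i, j])]
        for i, j in zip(*np.nonzero(mat))
    ]
    rows = []
    for fid in exp.feature_ids:
        md = None
        if exp.taxonomy is not None:
            lineage = []
            for rank in exp.taxonomy.ranks:
                label = exp.taxonomy.data.loc[fid, rank]
                prefix = next(k for k, v in GREENGENES_PREFIXES.items() if v == rank)
                lineage.append(f"{prefix}__{'' if label == UNCLASSIFIED else label}")
            md = {"taxonomy": lineage}
        rows.append({"id": str(fid), "metadata": md})
    columns = []
    for sid in exp.sample_ids:
        md = {
            k: (None if pd.isna(v) else (v.item() if hasattr(v, "item") else v))
            for k, v in exp.sample_metadata.loc[sid].items()
        }
        columns.append({"id": str(sid), "metadata": md or None})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "otukit",
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [exp.n_features, exp.n_samples],
        "rows": rows,
        "columns": columns,
        "data": data,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# PathoScope reports

def read_pathoscope_reports(
    paths,
    id_column: str = PATHOSCOPE_ID_COLUMN,
    count_column: str = PATHOSCOPE_COUNT_COLUMN,
) -> MicrobiomeExperiment:
    """Merge per-sample read-assignment reports into one experiment.

    The union of genome ids across files forms the feature set (absent taxa
    get count 0); each file's sample id is its filename stem; duplicate taxon
    rows within one report are summed with a warning. Taxonomy is left absent
    (no network lookup is performed); taxids remain embedded in the
    ``ti|<taxid>`` feature ids.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("read_pathoscope_reports needs at least one file")
    per_sample = {}
    for p in paths:
        try:
            frame = pd.read_csv(p, sep="\t")
        except Exception as exc:
            raise ParseError(f"cannot parse report: {exc}", str(p)) from exc
        for col in (id_column, count_column):
            if col not in frame.columns:
                raise ParseError(f"missing column {col!r}", str(p))
        ids = frame[id_column].astype(str)
        if ids.str.len().eq(0).any():
            raise ParseError("empty genome id", str(p))
        counts = pd.to_numeric(frame[count_column], errors="coerce")
        if counts.isna().any() or (counts < 0).any():
            raise ParseError(f"invalid value in {count_column!r}", str(p))
        if ids.duplicated().any():
            warnings.warn(f"{p.name}: duplicate taxon rows summed", stacklevel=2)
        series = counts.groupby(ids, sort=False).sum()
        per_sample[p.stem] = series
    merged = pd.DataFrame(per_sample).fillna(0)
    merged = merged.sort_index()  # order-invariant feature axis
    return create_experiment(merged, metadata=pd.DataFrame(index=merged.columns))


def extract_taxids(feature_ids) -> pd.Series:
    """Pull NCBI taxids out of ``ti|<taxid>``-style genome identifiers."""
    out = {}
    for fid in feature_ids:
        m = TAXID_PATTERN.search(str(fid))
        out[str(fid)] = m.group(1) if m else None
    return pd.Series(out, name="taxid")


# ---------------------------------------------------------------------------
# session archive

def save_archive(exp: MicrobiomeExperiment, path, provenance=None) -> None:
    """Bundle an experiment into a single zip session archive."""
    path = str(path)
    manifest = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "ranks": list(exp.taxonomy.ranks) if exp.taxonomy is not None else [],
        "has_taxonomy": exp.taxonomy is not None,
        "n_features": exp.n_features,
        "n_samples": exp.n_samples,
        "created": datetime.now(timezone.utc).isoformat(),
        "provenance": list(provenance or []),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("counts.tsv", exp.counts.to_csv(sep="\t"))
        zf.writestr("metadata.tsv", exp.sample_metadata.to_csv(sep="\t"))
        if exp.taxonomy is not None:
            zf.writestr("taxonomy.tsv", exp.taxonomy.data.to_csv(sep="\t"))


def load_archive(path) -> MicrobiomeExperiment:
    """Load a session archive, validating version and members."""
    path = str(path)
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        raise ParseError(f"not a session archive: {exc}", path) from exc
    with zf:
        names = set(zf.namelist())
        if "manifest.json" not in names:
            raise ParseError("archive missing manifest.json", path)
        manifest = json.loads(zf.read("manifest.json"))
        version = str(manifest.get("format_version", ""))
        major = version.split(".")[0]
        if major != ARCHIVE_FORMAT_VERSION.split(".")[0]:
            raise VersionError(
                f"archive format version {version!r} not supported "
                f"(this build reads major version "
                f"{ARCHIVE_FORMAT_VERSION.split('.')[0]})",
                path,
            )
        for member in ("counts.tsv", "metadata.tsv"):
            if member not in names:
                raise ParseError(f"archive missing member {member!r}", path)
        import io as _io

        counts = pd.read_csv(_io.BytesIO(zf.read("counts.tsv")), sep="\t",
                             index_col=0)
        metadata = pd.read_csv(_io.BytesIO(zf.read("metadata.tsv")), sep="\t",
                               index_col=0)
        taxonomy = None
        if manifest.get("has_taxonomy") and "taxonomy.tsv" in names:
            taxonomy = pd.read_csv(_io.BytesIO(zf.read("taxonomy.tsv")),
                                   sep="\t", index_col=0, dtype=str)
    # metadata-only archives produce an empty-column frame with object dtype
    if metadata.shape[1] == 0:
        metadata = pd.DataFrame(index=counts.columns.astype(str))
    return create_experiment(counts, taxonomy=taxonomy, metadata=metadata)


def write_distance_matrix(D, path) -> None:
    """Write a DistanceMatrix as a square TSV with header ids."""
    D.to_frame().to_csv(str(path), sep="\t")


def read_distance_matrix(path, metric: str = "bray_curtis"):
    """Read a square TSV distance matrix."""
    from .diversity import DistanceMatrix

    frame = pd.read_csv(str(path), sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(dtype=float),
                          tuple(str(c) for c in frame.columns), metric)
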