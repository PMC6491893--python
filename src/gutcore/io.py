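"""Reading OTU / taxonomy / metadata files, OTU QC filtering, genus collapse
and relative-abundance computation.

Conventions: count and abundance tables are pandas DataFrames with taxa on the
rows and samples on the columns (the usual orientation of tab-delimited OTU
tables).  Reads that could not be assigned to a genus at the required
classifier confidence are pooled into a residual that is excluded from the
genus list but kept in every sample's denominator, so relative abundances are
fractions of the sample's *total* filtered reads.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

REQUIRED_METADATA_COLUMNS = ("dataset_id", "age_weeks", "sex", "strain", "health")

__all__ = [
    "OtuTable",
    "GenusCountTable",
    "GenusAbundanceTable",
    "TaxonomyMap",
    "ParseError",
    "UNASSIGNED",
    "REQUIRED_METADATA_COLUMNS",
    "read_otu_table",
    "read_taxonomy",
    "read_metadata",
    "filter_otus",
    "collapse_to_genus",
    "to_relative",
]


class ParseError(ValueError):
    """Malformed input file (carries the offending line number when known)."""


@dataclass
class OtuTable:
    counts: pd.DataFrame  # OTU x sample, non-negative integers
    flags: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate OTU ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("OTU counts must be integers")
        if (vals < 0).any():
            raise ValueError("OTU counts must be non-negative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other):
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and {
            k: v for k, v in self.flags.items() if v
        } == {k: v for k, v in other.flags.items() if v}


@dataclass
class GenusCountTable:
    counts: pd.DataFrame  # genus x sample
    residual: pd.Series  # genus-unassigned reads per sample
    phylum: dict[str, str] = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.residual


@dataclass
class GenusAbundanceTable:
    rel_abund: pd.DataFrame  # genus x sample, fractions of total filtered reads
    denominators: pd.Series  # per-sample total filtered reads (incl. residual)
    phylum: dict[str, str] = field(default_factory=dict)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.rel_abund.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel_abund.columns)


@dataclass
class TaxonomyMap:
    assignments: dict[str, str]  # otu -> genus name or UNASSIGNED
    phylum: dict[str, str] = field(default_factory=dict)  # genus -> phylum

    def __getitem__(self, otu: str) -> str:
        return self.assignments[otu]


def _parse_int(token: str, lineno: int, path) -> int:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric count {token!r}") from None
    if not math.isfinite(value) or value != int(value):
        raise ParseError(f"{path}:{lineno}: non-integer count {token!r}")
    if value < 0:
        raise ParseError(f"{path}:{lineno}: negative count {token!r}")
    return int(value)


def _read_otu_tsv(path) -> OtuTable:
    header: list[str] | None = None
    flag_col: int | None = None
    ids, rows = [], []
    flags: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                # allow the QIIME-classic "#OTU ID" leader
                header = fields
                if header[-1].lower() == "flags":
                    flag_col = len(header) - 1
                continue
            expect = len(header)
            if len(fields) != expect:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {expect})"
                )
            otu = fields[0]
            if flag_col is not None:
                raw = fields[flag_col].strip()
                if raw:
                    flags[otu] = frozenset(raw.replace(",", ";").split(";"))
                data = fields[1:flag_col]
            else:
                data = fields[1:]
            ids.append(otu)
            rows.append([_parse_int(t, lineno, path) for t in data])
    if header is None or not ids:
        raise ParseError(f"{path}: no OTUs")
    samples = header[1:flag_col] if flag_col is not None else header[1:]
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=ids, columns=samples
    )
    counts.index.name = "otu"
    return OtuTable(counts=counts, flags=flags)


def _read_otu_biom(path) -> OtuTable:
    """Minimal BIOM v1 (JSON) reader — dense and sparse matrix types."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = doc.get("rows", [])
    cols = doc.get("columns", [])
    if not rows:
        raise ParseError(f"{path}: no OTUs")
    ids = [r["id"] for r in rows]
    samples = [c["id"] for c in cols]
    shape = doc.get("shape", [len(ids), len(samples)])
    mat = np.zeros((shape[0], shape[1]))
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    if not np.all(np.isfinite(mat)) or np.any(mat < 0) or np.any(mat != np.round(mat)):
        raise ParseError(f"{path}: counts must be non-negative integers")
    flags = {}
    for r in rows:
        meta = r.get("metadata") or {}
        raw = meta.get("flags")
        if raw:
            flags[r["id"]] = frozenset(raw)
    counts = pd.DataFrame(mat.astype(np.int64), index=ids, columns=samples)
    counts.index.name = "otu"
    return OtuTable(counts=counts, flags=flags)


def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table from TSV or BIOM v1 (JSON)."""
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom":
        return _read_otu_biom(path)
    raise ValueError(f"unknown OTU table format {format!r}")


def read_taxonomy(path, confidence_threshold: float) -> TaxonomyMap:
    """Parse RDP-classifier fixed-rank output into an OTU->genus map.

    A genus assignment is kept iff its genus-rank confidence is >= the
    threshold (inclusive — the classifier names the admitted boundary);
    otherwise, and when the genus rank is missing, the OTU maps to
    ``UNASSIGNED``.  The threshold differs by sequencing protocol (0.5 for
    pyrosequenced V3 reads, 0.8 for V3-V4 MiSeq reads), hence a per-file
    argument.
    """
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must lie in [0, 1]")
    assignments: dict[str, str] = {}
    phylum: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            otu = fields[0]
            rest = fields[1:]
            # tolerate the optional empty / "-" orientation field RDP emits
            if rest and rest[0] in ("", "-", "+"):
                rest = rest[1:]
            ranks: dict[str, tuple[str, float]] = {}
            for i in range(0, len(rest) - 2, 3):
                name, rank, conf = rest[i], rest[i + 1], rest[i + 2]
                try:
                    ranks[rank.lower()] = (name, float(conf))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: bad confidence {conf!r}"
                    ) from None
            if "genus" not in ranks:
                logger.info("%s:%d: OTU %s has no genus rank; UNASSIGNED", path, lineno, otu)
                assignments[otu] = UNASSIGNED
                continue
            genus, conf = ranks["genus"]
            if conf >= confidence_threshold:
                assignments[otu] = genus
                if "phylum" in ranks:
                    phylum[genus] = ranks["phylum"][0]
            else:
                assignments[otu] = UNASSIGNED
    return TaxonomyMap(assignments=assignments, phylum=phylum)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV; indexed by sample_id, required columns enforced.

    Any column beyond the required ones is treated as a host physiological
    parameter and coerced to numeric (non-parsable entries become NaN).
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in meta.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    if (meta["health"].isna() | (meta["health"].str.strip() == "")).any():
        raise ParseError(f"{path}: empty health label")
    meta = meta.set_index("sample_id")
    for col in meta.columns:
        if col not in REQUIRED_METADATA_COLUMNS:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    return meta


def filter_otus(table: OtuTable, min_reads: int = 10, min_sample_frac: float = 0.01) -> OtuTable:
    """Apply the upstream OTU quality filters.

    Removes OTUs (i) flagged as chimera or singleton by the upstream
    clustering, (ii) with fewer than `min_reads` total reads, and (iii)
    present (count >= 1) in fewer than ceil(min_sample_frac * n_samples)
    samples.  The sample set is unchanged; idempotent.
    """
    counts = table.counts
    n_samples = counts.shape[1]
    min_present = math.ceil(min_sample_frac * n_samples)
    flagged = {
        otu
        for otu, fl in table.flags.items()
        if fl & {"chimera", "singleton"}
    }
    keep = []
    for otu in counts.index:
        if otu in flagged:
            continue
        row = counts.loc[otu]
        if row.sum() < min_reads:
            continue
        if int((row >= 1).sum()) < min_present:
            continue
        keep.append(otu)
    if not keep:
        raise ValueError("empty after filtering: no OTU passed the QC rules")
    flags = {o: table.flags[o] for o in keep if o in table.flags}
    return OtuTable(counts=counts.loc[keep].copy(), flags=flags)


def collapse_to_genus(table: OtuTable, taxonomy: TaxonomyMap | Mapping[str, str]) -> GenusCountTable:
    """Sum OTU counts per (genus, sample); unassigned reads go to the residual."""
    if isinstance(taxonomy, TaxonomyMap):
        mapping = taxonomy.assignments
        phylum = dict(taxonomy.phylum)
    else:
        mapping = dict(taxonomy)
        phylum = {}
    genus_of = []
    for otu in table.counts.index:
        g = mapping.get(otu)
        if g is None:
            logger.warning("OTU %s missing from taxonomy; treated as UNASSIGNED", otu)
            g = UNASSIGNED
        genus_of.append(g)
    grouped = table.counts.groupby(pd.Index(genus_of, name="genus"), sort=True).sum()
    if UNASSIGNED in grouped.index:
        residual = grouped.loc[UNASSIGNED]
        grouped = grouped.drop(index=UNASSIGNED)
    else:
        residual = pd.Series(0, index=table.counts.columns, dtype=np.int64)
    residual.name = "residual"
    phylum = {g: phylum.get(g, "") for g in grouped.index}
    return GenusCountTable(counts=grouped, residual=residual, phylum=phylum)


def to_relative(genus_counts: GenusCountTable) -> GenusAbundanceTable:
    """Relative abundances with per-sample denominators = total filtered reads
    (assigned + residual)."""
    denom = genus_counts.totals.astype(float)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(
            f"zero-read sample(s): {', '.join(map(str, zero.index[:5]))}"
        )
    rel = genus_counts.counts.astype(float).div(denom, axis=1)
    return GenusAbundanceTable(
        rel_abund=rel, denominators=denom, phylum=dict(genus_counts.phylum)
    )
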