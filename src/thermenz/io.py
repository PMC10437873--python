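"""Readers and writers for the external tables the pipeline consumes.

The pipeline never runs annotation tools itself; it parses their output
dialects: dbcan-style CAZyme overview tables, DRAM-style annotation tables
(MEROPS peptidase families and EC numbers), SignalP-style secretion
summaries, prokka-style GFF3 gene maps, and per-contig read-coverage
tables. All tabular formats are plain TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import pandas as pd

SCHEMES = ("CAZY", "MEROPS", "EC")

_CAZY_LABEL = re.compile(r"^(GH|GT|PL|CE|AA|CBM)\d+$")
_MEROPS_LABEL = re.compile(r"^[MSCANTUGP]\d+$")
_EC_LABEL = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


class FormatError(ValueError):
    """A file does not match the expected dialect."""


class ParseError(ValueError):
    """A field inside an otherwise well-formed file cannot be parsed."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

def sample_type_from_id(sample_id: str) -> str | None:
    """Fluid/sediment from the trailing F/S of a sample identifier."""
    if sample_id.endswith("F"):
        return "fluid"
    if sample_id.endswith("S"):
        return "sediment"
    return None


@dataclass(frozen=True)
class SiteMetadata:
    """One spring site (or sample) with its physicochemical context.

    ``temperature`` (degC) and ``pH`` are ``None`` when not measured; they
    are never imputed.
    """

    abbrev: str
    sample_name: str
    site_name: str = ""
    region: str = ""
    province: str = ""
    latitude: float | None = None
    longitude: float | None = None
    temperature: float | None = None
    pH: float | None = None

    def __post_init__(self) -> None:
        if self.temperature is not None and not 0.0 <= self.temperature <= 110.0:
            raise ValueError(
                f"temperature {self.temperature} outside [0, 110] for {self.abbrev}"
            )
        if self.pH is not None and not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH {self.pH} outside [0, 14] for {self.abbrev}")

    @property
    def sample_type(self) -> str | None:
        return sample_type_from_id(self.sample_name) or sample_type_from_id(self.abbrev)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's enzyme-classification call under one scheme.

    ``labels`` holds the family labels supported for this gene (CAZy family
    like GH23, MEROPS family like M23, or a dotted EC quadruple).
    ``tool_support`` names the callers whose columns were non-empty.
    """

    gene_id: str
    scheme: str
    labels: tuple[str, ...]
    tool_support: frozenset = frozenset()
    secreted: bool = False
    contig_id: str | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not self.labels:
            raise ValueError(f"gene {self.gene_id}: empty label set")
        pattern = {"CAZY": _CAZY_LABEL, "MEROPS": _MEROPS_LABEL, "EC": _EC_LABEL}[self.scheme]
        for lab in self.labels:
            if not pattern.match(lab):
                raise ValueError(
                    f"gene {self.gene_id}: label {lab!r} invalid for scheme {self.scheme}"
                )


@dataclass(frozen=True)
class ContigCoverage:
    contig_id: str
    mean_depth: float
    length: int

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError(f"contig {self.contig_id}: negative depth {self.mean_depth}")
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id}: length {self.length} < 1")


@dataclass(frozen=True)
class AssemblyStats:
    sample_id: str
    total_length: int
    n_contigs: int

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError(f"{self.sample_id}: total_length must be > 0")


# ---------------------------------------------------------------------------
# site metadata
# ---------------------------------------------------------------------------

_METADATA_COLS = [
    "abbrev", "sample_name", "site_name", "region",
    "latitude", "longitude", "province", "temperature", "pH",
]


def _missing(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return True
    s = str(value).strip()
    return s == "" or s.upper() == "NM" or s.lower() == "nan"


def _opt_float(value, what: str, row: int) -> float | None:
    if _missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: cannot parse {what} value {value!r}") from None


def read_site_metadata(path) -> list[SiteMetadata]:
    """Read a site-metadata TSV; 'NM' and blank numeric fields become None."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "abbrev" not in cols or "sample_name" not in cols:
        raise FormatError(f"{path}: need 'abbrev' and 'sample_name' columns")

    def get(row, name, default=""):
        return row[cols[name]] if name in cols else default

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        records.append(
            SiteMetadata(
                abbrev=get(row, "abbrev"),
                sample_name=get(row, "sample_name"),
                site_name=get(row, "site_name"),
                region=get(row, "region"),
                province=get(row, "province"),
                latitude=_opt_float(get(row, "latitude", None), "latitude", i),
                longitude=_opt_float(get(row, "longitude", None), "longitude", i),
                temperature=_opt_float(get(row, "temperature", None), "temperature", i),
                pH=_opt_float(get(row, "ph", None), "pH", i),
            )
        )
    return records


def write_site_metadata(records: list[SiteMetadata], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "abbrev": r.abbrev, "sample_name": r.sample_name,
            "site_name": r.site_name, "region": r.region,
            "latitude": "" if r.latitude is None else repr(r.latitude),
            "longitude": "" if r.longitude is None else repr(r.longitude),
            "province": r.province,
            "temperature": "NM" if r.temperature is None else repr(r.temperature),
            "pH": "NM" if r.pH is None else repr(r.pH),
        })
    pd.DataFrame(rows, columns=_METADATA_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CAZyme overview tables (dbcan dialect)
# ---------------------------------------------------------------------------

_NOT_TOOL_COLS = {"#ofTools", "EC#", "Signalp", "#oftools", "ec#"}


def truncate_subfamily(token: str) -> str:
    """'GH13_20(24-350)' -> 'GH13'. Family-level labels pass unchanged."""
    token = re.sub(r"\(.*?\)", "", token).strip()
    return token.split("_", 1)[0]


def _parse_family_cell(cell: str) -> list[str]:
    if _missing(cell) or cell.strip() in {"-", "N"}:
        return []
    out = []
    for tok in re.split(r"[+,]", cell):
        fam = truncate_subfamily(tok)
        if fam:
            out.append(fam)
    return out


def read_cazyme_overview(path) -> list[GeneAnnotation]:
    """Parse a dbcan-style overview table into CAZY annotations.

    No filtering happens here: every row becomes a record whose
    ``tool_support`` reflects which caller columns carried a family call.
    Subfamily suffixes (GH13_20) are truncated to the family (GH13).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_col = next((c for c in df.columns if "gene" in c.lower()), None)
    if gene_col is None:
        raise FormatError(f"{path}: no gene-id column found")
    tool_cols = [c for c in df.columns if c != gene_col and c not in _NOT_TOOL_COLS]

    records = []
    for _, row in df.iterrows():
        labels: list[str] = []
        support = set()
        for tool in tool_cols:
            fams = _parse_family_cell(row[tool])
            if fams:
                support.add(tool)
                for f in fams:
                    if f not in labels:
                        labels.append(f)
        if not labels:
            continue
        records.append(
            GeneAnnotation(
                gene_id=row[gene_col], scheme="CAZY",
                labels=tuple(labels), tool_support=frozenset(support),
            )
        )
    return records


# ---------------------------------------------------------------------------
# DRAM-style annotation tables (MEROPS + EC)
# ---------------------------------------------------------------------------

def read_dram_annotations(path) -> list[GeneAnnotation]:
    """Parse a DRAM-style annotation table into MEROPS and EC records.

    Emits one record per (gene, scheme, label); EC labels are not
    restricted to hydrolases here (that is a filtering decision).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_col = next((c for c in df.columns if "gene" in c.lower()), df.columns[0])
    pep_cols = [c for c in df.columns if "peptidase" in c.lower() or "merops" in c.lower()]
    ec_cols = [c for c in df.columns if c.lower() in {"ec_number", "ec", "ec#"}]

    records = []
    for _, row in df.iterrows():
        gene = row[gene_col]
        for col in pep_cols:
            if _missing(row[col]):
                continue
            for tok in re.split(r"[;,]", row[col]):
                tok = tok.strip().split(".", 1)[0]  # M23.001 -> M23
                if tok:
                    records.append(GeneAnnotation(gene, "MEROPS", (tok,),
                                                  frozenset({"DRAM"})))
        for col in ec_cols:
            if _missing(row[col]):
                continue
            for tok in re.split(r"[;,]", row[col]):
                tok = tok.strip().removeprefix("EC:").strip()
                if tok:
                    records.append(GeneAnnotation(gene, "EC", (tok,),
                                                  frozenset({"DRAM"})))
    return records


# ---------------------------------------------------------------------------
# secretion summaries (SignalP dialect)
# ---------------------------------------------------------------------------

_SECRETED_TRUE = {"y", "yes", "true", "1"}
_SECRETED_FALSE = {"n", "no", "false", "0", "other", "-", ""}


def read_secretion_flags(path, column: str | None = None) -> set[str]:
    """Gene ids flagged as carrying a signal peptide.

    Any yes/no-style column works; SignalP 'Prediction' values starting
    with 'SP' count as secreted and 'OTHER' as not. ``column`` overrides
    autodetection.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return set()
    gene_col = next((c for c in df.columns if "gene" in c.lower() or c.lower() == "id"),
                    df.columns[0])
    if column is None:
        candidates = [c for c in df.columns
                      if c.lower() in {"prediction", "secreted", "signalp", "sp"}]
        if not candidates:
            candidates = [c for c in df.columns if c != gene_col]
        if not candidates:
            raise FormatError(f"{path}: no secretion call column found")
        column = candidates[0]

    flagged = set()
    for _, row in df.iterrows():
        val = str(row[column]).strip()
        low = val.lower()
        if low.startswith("sp") or low in _SECRETED_TRUE:
            flagged.add(row[gene_col])
        elif low not in _SECRETED_FALSE:
            # numeric score column: treat >= 0.5 as secreted
            try:
                if float(val) >= 0.5:
                    flagged.add(row[gene_col])
            except ValueError:
                pass
    return flagged


# ---------------------------------------------------------------------------
# GFF3 gene maps
# ---------------------------------------------------------------------------

_GFF_FEATURES = {"gene", "CDS", "mRNA"}


def read_gene_map(path) -> dict[str, str]:
    """Map feature ID -> seqid from a (prokka-style) GFF3 file.

    The embedded ``##FASTA`` section, if any, is ignored. A feature ID seen
    on two different contigs is an error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in _GFF_FEATURES:
                continue
            seqid, attrs = parts[0], parts[8]
            m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
            if not m:
                continue
            gid = m.group(1)
            if gid in mapping and mapping[gid] != seqid:
                raise FormatError(
                    f"{path}: feature {gid} maps to both {mapping[gid]} and {seqid}"
                )
            mapping[gid] = seqid
    return mapping


def infer_contig(gene_id: str) -> str:
    """Prokka convention: the gene id up to its last '_' names the contig."""
    if "_" not in gene_id:
        raise KeyError(f"cannot infer contig from gene id {gene_id!r}")
    return gene_id.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# coverage tables
# ---------------------------------------------------------------------------

def read_coverage(path) -> list[ContigCoverage]:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    try:
        cid = cols.get("contig_id") or cols["contig"]
        depth = cols.get("mean_depth") or cols["depth"]
        length = cols["length"]
    except KeyError:
        raise FormatError(f"{path}: need contig id, mean depth and length columns") from None
    return [
        ContigCoverage(str(r[cid]), float(r[depth]), int(r[length]))
        for _, r in df.iterrows()
    ]


def write_coverage(records: list[ContigCoverage], path) -> None:
    pd.DataFrame(
        [{"contig_id": r.contig_id, "mean_depth": repr(r.mean_depth), "length": r.length}
         for r in records],
        columns=["contig_id", "mean_depth", "length"],
    ).to_csv(path, sep="\t", index=False)


def read_coverage_from_depth(path, lengths: dict[str, int]) -> list[ContigCoverage]:
    """Aggregate a samtools-depth style per-base table (contig, pos, depth).

    Positions absent from the table count as zero depth; the mean is taken
    over the full contig length supplied in ``lengths``.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "pos", "depth"])
    if (df["depth"] < 0).any():
        raise ParseError(f"{path}: negative per-base depth")
    sums = df.groupby("contig")["depth"].sum()
    return [
        ContigCoverage(cid, float(sums.get(cid, 0.0)) / length, length)
        for cid, length in lengths.items()
    ]


def read_assembly_stats(path) -> list[AssemblyStats]:
    df = pd.read_csv(path, sep="\t")
    return [
        AssemblyStats(str(r["sample_id"]), int(r["total_length"]), int(r["n_contigs"]))
        for _, r in df.iterrows()
    ]


def write_assembly_stats(records: list[AssemblyStats], path) -> None:
    pd.DataFrame(
        [{"sample_id": r.sample_id, "total_length": r.total_length,
          "n_contigs": r.n_contigs} for r in records]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# joining helpers
# ---------------------------------------------------------------------------

def attach_secretion(annots: list[GeneAnnotation], secreted_ids: set[str]) -> list[GeneAnnotation]:
    """Return copies with ``secreted`` set from a flag set."""
    return [replace(a, secreted=a.gene_id in secreted_ids) for a in annots]


def attach_contigs(annots: list[GeneAnnotation],
                   gene_map: dict[str, str] | None = None) -> list[GeneAnnotation]:
    """Resolve each gene's host contig via the GFF map, falling back to the
    prokka id-prefix convention when the gene is absent from the map."""
    out = []
    for a in annots:
        if gene_map is not None and a.gene_id in gene_map:
            cid = gene_map[a.gene_id]
        else:
            cid = infer_contig(a.gene_id)
        out.append(replace(a, contig_id=cid))
    return out
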