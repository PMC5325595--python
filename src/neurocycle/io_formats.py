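"""Domain types and readers/writers for the pipeline's external formats.

Expression tables are TSV with sample metadata embedded in the column
headers as ``sample_id|group|replicate_set|zt`` (a sidecar metadata TSV is
also accepted).  Gene models are read from GTF or BED12; aligned-read
3'-position records from BED6.  All coordinates are 0-based half-open
internally; GTF's 1-based closed intervals are converted on read.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Collection grids of the study design: lateral neurons (LNv, LNd) and the
#: dopaminergic outgroup (TH) sampled at ZT2..ZT22, dorsal DN1 neurons offset
#: by +1 h (ZT3..ZT23).  Six timepoints at 4-h spacing per replicate set.
DEFAULT_ZT_GRIDS: dict[str, tuple[float, ...]] = {
    "LNv": (2.0, 6.0, 10.0, 14.0, 18.0, 22.0),
    "LNd": (2.0, 6.0, 10.0, 14.0, 18.0, 22.0),
    "DN1": (3.0, 7.0, 11.0, 15.0, 19.0, 23.0),
    "TH": (2.0, 6.0, 10.0, 14.0, 18.0, 22.0),
}

CIRCADIAN_GROUPS = ("LNv", "LNd", "DN1")
OUTGROUP = "TH"

REPLICATE_SETS = (1, 2)
TIMEPOINTS_PER_SET = 6
ZT_SPACING_H = 4.0


class FormatError(ValueError):
    """Malformed external file (header, record structure, coordinates)."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one library: neuron group, replicate time course, ZT."""

    sample_id: str
    group: str
    replicate_set: int
    zt: float

    def __post_init__(self) -> None:
        if not (0 <= self.zt < 24):
            raise ValueError(
                f"sample {self.sample_id!r}: zt must lie in [0, 24), got {self.zt}"
            )
        if self.replicate_set not in REPLICATE_SETS:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate_set must be 1 or 2, "
                f"got {self.replicate_set}"
            )

    def header_token(self) -> str:
        zt = int(self.zt) if float(self.zt).is_integer() else self.zt
        return f"{self.sample_id}|{self.group}|{self.replicate_set}|{zt}"

    @classmethod
    def from_header_token(cls, token: str) -> "SampleMeta":
        parts = token.split("|")
        if len(parts) != 4:
            raise FormatError(
                f"column header {token!r} is not 'sample_id|group|replicate_set|zt'"
            )
        sample_id, group, rep, zt = parts
        try:
            return cls(sample_id=sample_id, group=group,
                       replicate_set=int(rep), zt=float(zt))
        except ValueError as exc:
            raise FormatError(f"column header {token!r}: {exc}") from exc


class ExpressionMatrix:
    """Genes x samples matrix of reads-per-million values with metadata.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns;
    ``sample_meta`` is indexed by sample_id with columns group,
    replicate_set, zt.  Missing measurements are NaN; negative values are
    rejected.  Downstream stages that assume the full study design call
    :meth:`require_complete_grid`.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sample_id {dup!r}")
        if list(values.columns) != ids:
            raise ValueError("values columns must match sample metadata order")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        arr = values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value for gene {values.index[g]!r} "
                f"in sample {values.columns[s]!r}"
            )
        self.values = values.astype(float)
        self.samples = samples
        self.sample_meta = pd.DataFrame(
            {
                "group": [s.group for s in samples],
                "replicate_set": [s.replicate_set for s in samples],
                "zt": [s.zt for s in samples],
            },
            index=pd.Index(ids, name="sample_id"),
        )

    # -- basic introspection -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def sample_ids(self, group: str, replicate_set: int | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if s.group != group:
                continue
            if replicate_set is not None and s.replicate_set != replicate_set:
                continue
            out.append(s.sample_id)
        return out

    def zt_grid(self, group: str) -> tuple[float, ...]:
        zts = sorted({s.zt for s in self.samples if s.group == group})
        return tuple(zts)

    def group_values(self, group: str, replicate_set: int | None = None) -> pd.DataFrame:
        return self.values[self.sample_ids(group, replicate_set)]

    # -- validation ----------------------------------------------------------

    def require_complete_grid(self, group: str) -> None:
        """Fail fast unless `group` has 2 replicate sets x 6 ZTs at 4-h spacing."""
        for rep in REPLICATE_SETS:
            zts = sorted(
                s.zt for s in self.samples
                if s.group == group and s.replicate_set == rep
            )
            if len(zts) != TIMEPOINTS_PER_SET or len(set(zts)) != TIMEPOINTS_PER_SET:
                raise ValueError(
                    f"group {group!r} replicate set {rep}: expected "
                    f"{TIMEPOINTS_PER_SET} distinct ZTs, got {zts}"
                )
            gaps = np.diff(zts)
            if not np.allclose(gaps, ZT_SPACING_H):
                raise ValueError(
                    f"group {group!r} replicate set {rep}: ZTs {zts} are not "
                    f"at {ZT_SPACING_H}-h spacing"
                )
        sub = self.group_values(group)
        if sub.isna().any().any():
            raise ValueError(f"group {group!r} has missing (NA) values")

    def series(self, gene_id: str, group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (values, zts, replicate_sets) for one gene in one group,
        ordered by (replicate_set, zt)."""
        metas = sorted(
            (s for s in self.samples if s.group == group),
            key=lambda s: (s.replicate_set, s.zt),
        )
        ids = [s.sample_id for s in metas]
        vals = self.values.loc[gene_id, ids].to_numpy(dtype=float)
        zts = np.array([s.zt for s in metas])
        reps = np.array([s.replicate_set for s in metas])
        return vals, zts, reps


# ---------------------------------------------------------------------------
# Expression table I/O
# ---------------------------------------------------------------------------

def write_expression_table(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = matrix.values.copy()
    df.columns = [s.header_token() for s in matrix.samples]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression_table(
    path: str | os.PathLike, sample_sidecar: str | os.PathLike | None = None
) -> ExpressionMatrix:
    """Read a TSV expression table.

    Column headers normally encode metadata as
    ``sample_id|group|replicate_set|zt``; alternatively a sidecar TSV with
    columns sample_id/group/replicate_set/zt may be given and headers are
    then bare sample ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    if sample_sidecar is not None:
        meta = pd.read_csv(sample_sidecar, sep="\t")
        required = {"sample_id", "group", "replicate_set", "zt"}
        if not required.issubset(meta.columns):
            raise FormatError(
                f"{sample_sidecar}: sidecar must have columns {sorted(required)}"
            )
        by_id = {str(r.sample_id): r for r in meta.itertuples(index=False)}
        samples = []
        for col in df.columns:
            if col not in by_id:
                raise FormatError(f"{path}: column {col!r} missing from sidecar")
            r = by_id[col]
            samples.append(SampleMeta(str(r.sample_id), str(r.group),
                                      int(r.replicate_set), float(r.zt)))
    else:
        samples = [SampleMeta.from_header_token(c) for c in df.columns]
    df.columns = [s.sample_id for s in samples]
    for col, s in zip(df.columns, samples):
        colvals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & colvals.isna()
        if bad.any():
            gene = df.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value for gene {gene!r} in sample {s.sample_id!r}"
            )
        neg = colvals < 0
        if neg.any():
            gene = df.index[neg][0]
            raise FormatError(
                f"{path}: negative value for gene {gene!r} in sample {s.sample_id!r}"
            )
        df[col] = colvals
    return ExpressionMatrix(df, samples)


# ---------------------------------------------------------------------------
# Gene models (GTF / BED12) and read records (BED6)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """All isoforms of one gene: exon intervals, 0-based half-open, sorted.

    The 3' end of an isoform is its rightmost coordinate on the + strand and
    its leftmost on the - strand.  Distinct isoform 3' ends are all retained:
    alternative 3' UTRs (e.g. a short vs an extended UTR of the same
    neuropeptide gene in different neuron groups) produce distinct
    quantification windows.
    """

    gene_id: str
    chrom: str
    strand: str
    isoforms: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if not self.isoforms:
            raise FormatError(f"gene {self.gene_id!r}: no isoforms")
        for exons in self.isoforms:
            if not exons:
                raise FormatError(f"gene {self.gene_id!r}: isoform with no exons")
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise FormatError(
                        f"gene {self.gene_id!r}: exons overlap or unsorted"
                    )
            for s0, e0 in exons:
                if not (0 <= s0 < e0):
                    raise FormatError(
                        f"gene {self.gene_id!r}: bad exon interval ({s0},{e0})"
                    )

    def three_prime_ends(self) -> tuple[int, ...]:
        """Distinct genomic 3'-end positions over all isoforms."""
        ends = set()
        for exons in self.isoforms:
            if self.strand == "+":
                ends.add(exons[-1][1])
            else:
                ends.add(exons[0][0])
        return tuple(sorted(ends))

    def transcript_length(self, isoform: int) -> int:
        return sum(e - s for s, e in self.isoforms[isoform])

    def total_span(self) -> tuple[int, int]:
        start = min(ex[0][0] for ex in self.isoforms)
        end = max(ex[-1][1] for ex in self.isoforms)
        return start, end

    def is_intronless(self) -> bool:
        return all(len(exons) == 1 for exons in self.isoforms)


@dataclass(frozen=True)
class ReadRecord:
    """3'-terminal genomic position of a single aligned read (0-based)."""

    chrom: str
    strand: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"read position must be >= 0, got {self.pos}")
        if self.strand not in "+-":
            raise FormatError(f"unknown strand {self.strand!r}")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    # (gene_id, transcript_id) -> list of exon intervals; insertion-ordered
    exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{ln}: expected 9 GTF fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise FormatError(f"{path}:{ln}: missing gene_id/transcript_id")
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            if strand not in "+-":
                raise FormatError(f"{path}:{ln}: unknown strand {strand!r}")
            if gid in strands and strands[gid] != strand:
                raise FormatError(f"{path}:{ln}: gene {gid!r} on both strands")
            strands[gid], chroms[gid] = strand, chrom
            # GTF is 1-based closed; convert to 0-based half-open
            exons.setdefault((gid, tid), []).append((int(start) - 1, int(end)))
    models: dict[str, list[tuple[tuple[int, int], ...]]] = {}
    for (gid, _tid), ivs in exons.items():
        models.setdefault(gid, []).append(tuple(sorted(ivs)))
    return [
        GeneModel(gid, chroms[gid], strands[gid], tuple(isos))
        for gid, isos in models.items()
    ]


def _read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: expected 12 BED12 fields")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            if strand not in "+-":
                raise FormatError(f"{path}:{ln}: unknown strand {strand!r}")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{ln}: block counts disagree")
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(starts, sizes)
            )
            # name convention gene_id or gene_id.transcript: group by gene part
            gid = name.split(".", 1)[0]
            rec = per_gene.setdefault(gid, {"chrom": chrom, "strand": strand,
                                            "isoforms": []})
            if rec["strand"] != strand:
                raise FormatError(f"{path}:{ln}: gene {gid!r} on both strands")
            rec["isoforms"].append(exons)
    return [
        GeneModel(gid, rec["chrom"], rec["strand"], tuple(rec["isoforms"]))
        for gid, rec in per_gene.items()
    ]


def read_gene_models(path: str | os.PathLike, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from GTF or BED12 (auto-detected from extension)."""
    if fmt is None:
        lower = str(path).lower()
        fmt = "bed12" if lower.endswith((".bed", ".bed12")) else "gtf"
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def write_gene_models_gtf(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in models:
            for i, exons in enumerate(m.isoforms):
                tid = f"{m.gene_id}.{i + 1}"
                for s, e in exons:
                    fh.write(
                        f"{m.chrom}\tneurocycle\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f'gene_id "{m.gene_id}"; transcript_id "{tid}";\n'
                    )


def read_bed_reads(path: str | os.PathLike) -> list[ReadRecord]:
    """Read BED6 records of single-read 3'-terminal positions."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{ln}: expected 6 BED fields")
            out.append(ReadRecord(chrom=f[0], strand=f[5], pos=int(f[1])))
    return out


def write_bed_reads(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\tread{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    summary: Mapping | None = None,
) -> dict[str, str]:
    """Write result tables as TSVs (deterministic column order) plus an
    optional JSON summary of counts per class; returns name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[name] = path
    if summary is not None:
        path = os.path.join(out_dir, "summary.json")
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        written["summary"] = path
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
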