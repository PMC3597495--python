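"""Readers and writers for the tab-separated dialects used by the pipeline.

Formats
-------
segments
    ``#sample_id chrom start end copy_state n_markers`` (TSV). The canonical
    dialect is 0-based half-open; ``dialect="onebased"`` accepts 1-based
    inclusive coordinates (the convention of most array CNV-calling software)
    and converts on read.
pedigree
    ``#family_id sample_id father_id mother_id sex group affected height_sds
    proportionate syndromic prenatal_onset learning_disability``. Parent ids
    of ``0`` mean unknown; ``.`` marks missing values. Rows with both parents
    known define a trio.
genes
    BED-like: ``#chrom start end gene_id exons attributes`` where ``exons``
    is ``start-end,start-end,...`` and ``attributes`` is a ``;``-separated
    ``key=value`` list.
expression
    genes x samples matrix of log2 expression, first column ``gene_id``.
snps
    ``#chrom pos p`` per-SNP association p-values.
mlpa
    ``#probe_id locus sample_id ratio`` relative probe quantities.

All coordinates inside the package are 0-based half-open; conversion happens
only here.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    CALL_COLUMNS,
    CNVCall,
    GeneModel,
    SampleRecord,
    Trio,
    calls_to_frame,
    cnv_type_of,
)
from .errors import IntegrityError, LinkageError, ParseError, RareCNVError

SEGMENT_HEADER = "#sample_id\tchrom\tstart\tend\tcopy_state\tn_markers"
PED_HEADER = (
    "#family_id\tsample_id\tfather_id\tmother_id\tsex\tgroup\taffected\t"
    "height_sds\tproportionate\tsyndromic\tprenatal_onset\tlearning_disability"
)
GENE_HEADER = "#chrom\tstart\tend\tgene_id\texons\tattributes"
SNP_HEADER = "#chrom\tpos\tp"
MLPA_HEADER = "#probe_id\tlocus\tsample_id\tratio"

MISSING = "."

_GENE_FLAGS = (
    "growth_gene",
    "mgi_growth",
    "functional_candidate",
    "growth_tissue_expressed",
    "decipher_overlap",
)


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def _read_rows(path: str | Path, expected_header: str) -> list[tuple[int, list[str]]]:
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or lines[0].rstrip() != expected_header:
        raise ParseError(
            f"{path}: expected header {expected_header!r}, "
            f"got {(lines[0] if lines else '<empty file>')!r}"
        )
    rows = []
    ncol = len(expected_header.split("\t"))
    bad: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            bad.append(f"line {lineno}: expected {ncol} columns, got {len(parts)}")
            continue
        rows.append((lineno, parts))
    if bad:
        raise ParseError(f"{path}: malformed rows:\n" + "\n".join(bad))
    return rows


# ---------------------------------------------------------------------------
# segments


def read_segments(path: str | Path, dialect: str = "canonical") -> pd.DataFrame:
    """Read a segment TSV into the canonical call table.

    Parameters
    ----------
    dialect
        ``"canonical"`` for 0-based half-open coordinates, ``"onebased"``
        for 1-based inclusive input (converted to half-open on read).
    """
    if dialect not in ("canonical", "onebased"):
        raise ParseError(f"unknown segment dialect {dialect!r}")
    rows = _read_rows(path, SEGMENT_HEADER)
    calls: list[CNVCall] = []
    bad: list[str] = []
    for lineno, (sample, chrom, start, end, state, markers) in rows:
        try:
            s, e = int(start), int(end)
            if dialect == "onebased":
                s -= 1
            calls.append(
                CNVCall(
                    sample_id=sample,
                    chrom=chrom,
                    start=s,
                    end=e,
                    copy_state=int(state),
                    n_markers=int(markers),
                )
            )
        except (ValueError, RareCNVError) as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ParseError(f"{path}: invalid records:\n" + "\n".join(bad))
    return calls_to_frame(calls)


def write_segments(calls: pd.DataFrame | Iterable[CNVCall], path: str | Path) -> None:
    """Write the canonical 0-based half-open segment TSV."""
    if not isinstance(calls, pd.DataFrame):
        calls = calls_to_frame(calls)
    with open(path, "w") as fh:
        fh.write(SEGMENT_HEADER + "\n")
        for r in calls.itertuples(index=False):
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{int(r.start)}\t{int(r.end)}\t"
                f"{int(r.copy_state)}\t{int(r.n_markers)}\n"
            )


# ---------------------------------------------------------------------------
# pedigree


def _parse_bool(token: str) -> bool | None:
    if token == MISSING:
        return None
    if token in ("0", "1"):
        return token == "1"
    raise ValueError(f"expected 0/1/., got {token!r}")


def read_ped(path: str | Path) -> tuple[dict[str, SampleRecord], list[Trio]]:
    """Read a pedigree/affection table; returns samples and derived trios."""
    rows = _read_rows(path, PED_HEADER)
    samples: dict[str, SampleRecord] = {}
    parent_refs: list[tuple[int, str, str, str]] = []
    bad: list[str] = []
    for lineno, parts in rows:
        (fam, sid, father, mother, sex, group, affected, sds, prop, syn, pre, ld) = parts
        try:
            if sid in samples:
                raise ValueError(f"duplicate sample id {sid!r}")
            samples[sid] = SampleRecord(
                sample_id=sid,
                group=group,
                sex=sex,
                height_sds=None if sds == MISSING else float(sds),
                affected=bool(_parse_bool(affected)),
                proportionate=_parse_bool(prop),
                syndromic=_parse_bool(syn),
                prenatal_onset=_parse_bool(pre),
                learning_disability=_parse_bool(ld),
            )
            if father != "0" or mother != "0":
                parent_refs.append((lineno, sid, father, mother))
        except (ValueError, RareCNVError) as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ParseError(f"{path}: invalid records:\n" + "\n".join(bad))
    trios: list[Trio] = []
    for lineno, child, father, mother in parent_refs:
        if father == "0" or mother == "0":
            continue  # single known parent: no trio
        missing = [p for p in (father, mother) if p not in samples]
        if missing:
            raise LinkageError(
                f"{path} line {lineno}: trio for {child!r} references "
                f"missing sample(s) {missing}"
            )
        trios.append(
            Trio(
                child_id=child,
                mother_id=mother,
                father_id=father,
                mother_affected=samples[mother].affected,
                father_affected=samples[father].affected,
            )
        )
    return samples, trios


def write_ped(
    samples: Mapping[str, SampleRecord],
    trios: Iterable[Trio],
    path: str | Path,
) -> None:
    parent_of = {t.child_id: (t.father_id, t.mother_id) for t in trios}
    with open(path, "w") as fh:
        fh.write(PED_HEADER + "\n")
        for sid in samples:
            s = samples[sid]
            father, mother = parent_of.get(sid, ("0", "0"))
            fam = sid.split("-")[0]
            fh.write(
                "\t".join(
                    [
                        fam,
                        s.sample_id,
                        father,
                        mother,
                        s.sex,
                        s.group,
                        _fmt(s.affected),
                        _fmt(s.height_sds),
                        _fmt(s.proportionate),
                        _fmt(s.syndromic),
                        _fmt(s.prenatal_onset),
                        _fmt(s.learning_disability),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# genes


def read_genes(path: str | Path) -> list[GeneModel]:
    rows = _read_rows(path, GENE_HEADER)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    bad: list[str] = []
    for lineno, (chrom, start, end, gene_id, exons_s, attrs_s) in rows:
        try:
            if gene_id in seen:
                raise ValueError(f"duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            exons = tuple(
                (int(p.split("-")[0]), int(p.split("-")[1]))
                for p in exons_s.split(",")
                if p
            )
            attrs: dict[str, str] = {}
            if attrs_s != MISSING:
                for kv in attrs_s.split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    exons=exons,
                    hi_percentile=float(attrs.get("hi_percentile", 50.0)),
                    **{f: attrs.get(f, "0") == "1" for f in _GENE_FLAGS},
                )
            )
        except (ValueError, IndexError, RareCNVError) as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ParseError(f"{path}: invalid records:\n" + "\n".join(bad))
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(GENE_HEADER + "\n")
        for g in genes:
            exons = ",".join(f"{s}-{e}" for s, e in g.exons)
            attrs = ";".join(
                [f"{f}={'1' if getattr(g, f) else '0'}" for f in _GENE_FLAGS]
                + [f"hi_percentile={format(g.hi_percentile, '.6g')}"]
            )
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{exons}\t{attrs}\n")


# ---------------------------------------------------------------------------
# expression / SNPs / MLPA


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix (gene ids as index)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id'")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicated gene id(s): {sorted(set(dup))}")
    return df.set_index("gene_id")


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_snp_track(path: str | Path) -> pd.DataFrame:
    rows = _read_rows(path, SNP_HEADER)
    bad = []
    recs = []
    for lineno, (chrom, pos, p) in rows:
        try:
            pv = float(p)
            if not 0.0 < pv <= 1.0:
                raise ValueError(f"p-value {pv} outside (0, 1]")
            recs.append((chrom, int(pos), pv))
        except ValueError as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ParseError(f"{path}: invalid records:\n" + "\n".join(bad))
    df = pd.DataFrame(recs, columns=["chrom", "pos", "p"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_snp_track(snps: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(SNP_HEADER + "\n")
        for r in snps.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.pos)}\t{format(r.p, '.6g')}\n")


def read_mlpa(path: str | Path) -> pd.DataFrame:
    rows = _read_rows(path, MLPA_HEADER)
    recs = []
    bad = []
    for lineno, (probe, locus, sample, ratio) in rows:
        try:
            rv = float(ratio)
            if rv <= 0:
                raise ValueError(f"probe ratio must be positive, got {rv}")
            recs.append((probe, locus, sample, rv))
        except ValueError as exc:
            bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ParseError(f"{path}: invalid records:\n" + "\n".join(bad))
    return pd.DataFrame(recs, columns=["probe_id", "locus", "sample_id", "ratio"])


def write_mlpa(mlpa: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(MLPA_HEADER + "\n")
        for r in mlpa.itertuples(index=False):
            fh.write(
                f"{r.probe_id}\t{r.locus}\t{r.sample_id}\t{format(r.ratio, '.6g')}\n"
            )


# ---------------------------------------------------------------------------
# packaged worked-example fixture


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged 20-CNV prioritization table (worked example).

    Twenty candidate CNVs from a short-stature cohort with their inheritance,
    type, locus, printed position (Mb, hg19), size in kb and per-CNV lines of
    evidence. Positions are stored as printed (rounded to 0.1 Mb); sizes come
    from the table's own size column, not from the rounded positions.
    """
    res = importlib.resources.files("rarecnv").joinpath("data/table2.tsv")
    with importlib.resources.as_file(res) as fp:
        df = pd.read_csv(
            fp,
            sep="\t",
            na_values=[MISSING],
            dtype={"gwas_significant": "int64"},
        )
    df.columns = [df.columns[0].lstrip("#")] + list(df.columns[1:])
    # integrity checks on the packaged resource
    if len(df) != 20:
        raise IntegrityError(f"fixture must contain 20 records, found {len(df)}")
    counts = df["cnv_type"].value_counts()
    if counts.get("gain", 0) != 10 or counts.get("loss", 0) != 10:
        raise IntegrityError("fixture must contain 10 gains and 10 losses")
    if (df["inheritance"] == "de_novo").sum() != 7:
        raise IntegrityError("fixture must contain 7 de novo records")
    if df["size_kb"].min() != 109 or df["size_kb"].max() != 14229:
        raise IntegrityError("fixture sizes must span [109, 14229] kb")
    df["gwas_significant"] = df["gwas_significant"].astype(bool)
    return df
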