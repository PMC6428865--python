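"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular artifacts are TSV. Readers validate strictly and report the
offending line; writer/reader pairs are exact inverses on valid data.
Internally all coordinates are 0-based half-open; the GFF3 reader converts
from 1-based inclusive spans at the boundary.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CodonCoverage,
    CountTable,
    GeneAnnotation,
    PARSProfile,
    RateRecord,
    SampleMeta,
    TEResult,
    TruthRecord,
)

_FLOAT_FMT = "%.6g"


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return _FLOAT_FMT % v
    return str(v)


# ---------------------------------------------------------------------------
# counts + sample metadata


def write_counts(table: CountTable, counts_path, meta_path) -> None:
    with open(counts_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(table.sample_ids) + "\n")
        for gid, row in zip(table.gene_ids, table.counts):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tassay\tcondition\treplicate\n")
        for s in table.samples:
            fh.write(f"{s.sample_id}\t{s.assay}\t{s.condition}\t{s.replicate}\n")


def read_counts(counts_path, meta_path) -> CountTable:
    meta = {}
    with open(meta_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "assay", "condition", "replicate"]
        if header != expected:
            raise ValueError(f"{meta_path}: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{meta_path}:{lineno}: expected 4 fields, got {len(parts)}")
            sid, assay, cond, rep = parts
            if sid in meta:
                raise ValueError(f"{meta_path}:{lineno}: duplicate sample id {sid!r}")
            try:
                rep_i = int(rep)
            except ValueError:
                raise ValueError(f"{meta_path}:{lineno}: replicate {rep!r} is not an integer")
            meta[sid] = SampleMeta(sid, assay, cond, rep_i)

    with open(counts_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene_id":
            raise ValueError(f"{counts_path}:1: first column must be 'gene_id'")
        sample_ids = header[1:]
        for sid in sample_ids:
            if sid not in meta:
                raise ValueError(
                    f"{counts_path}:1: sample {sid!r} absent from metadata {meta_path}"
                )
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{counts_path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            gid = parts[0]
            if gid in seen:
                raise ValueError(f"{counts_path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            row = []
            for col, tok in enumerate(parts[1:]):
                try:
                    val = int(tok)
                except ValueError:
                    raise ValueError(
                        f"{counts_path}:{lineno}: non-integer count {tok!r} "
                        f"in column {sample_ids[col]!r}"
                    )
                if val < 0:
                    raise ValueError(
                        f"{counts_path}:{lineno}: negative count {val} "
                        f"in column {sample_ids[col]!r} (gene {gid!r})"
                    )
                row.append(val)
            gene_ids.append(gid)
            rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(gene_ids), len(sample_ids))
    return CountTable(gene_ids, [meta[s] for s in sample_ids], counts)


# ---------------------------------------------------------------------------
# gene models

_ANN_COLS = ["gene_id", "utr5_length", "cds_length", "utr3_length", "is_membrane", "srp_class"]


def write_gene_models_tsv(annotations: Sequence[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_COLS) + "\n")
        for a in annotations:
            fh.write(
                f"{a.gene_id}\t{a.utr5_length}\t{a.cds_length}\t{a.utr3_length}\t"
                f"{'1' if a.is_membrane else '0'}\t{a.srp_class}\n"
            )


def write_gene_models_gff3(annotations: Sequence[GeneAnnotation], path) -> None:
    """Lay each transcript on its own synthetic contig, + strand, 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            seqid = f"ctg_{a.gene_id}"
            start = 1
            attrs_extra = f";membrane={'1' if a.is_membrane else '0'};srp_class={a.srp_class}"
            fh.write(
                f"{seqid}\tribodelta\tgene\t{start}\t{a.total_length}\t.\t+\t.\t"
                f"ID={a.gene_id}{attrs_extra}\n"
            )
            pos = 1
            if a.utr5_length:
                fh.write(
                    f"{seqid}\tribodelta\tfive_prime_UTR\t{pos}\t{pos + a.utr5_length - 1}"
                    f"\t.\t+\t.\tParent={a.gene_id}\n"
                )
                pos += a.utr5_length
            fh.write(
                f"{seqid}\tribodelta\tCDS\t{pos}\t{pos + a.cds_length - 1}\t.\t+\t0\t"
                f"Parent={a.gene_id}\n"
            )
            pos += a.cds_length
            if a.utr3_length:
                fh.write(
                    f"{seqid}\tribodelta\tthree_prime_UTR\t{pos}\t{pos + a.utr3_length - 1}"
                    f"\t.\t+\t.\tParent={a.gene_id}\n"
                )


def read_gene_models(path, dialect: str = "tsv") -> list[GeneAnnotation]:
    """Load gene models from the TSV dialect or from GFF3.

    GFF3 lengths are the summed spans of five_prime_UTR / CDS /
    three_prime_UTR features grouped by Parent (1-based inclusive
    coordinates, so a span start..end contributes end - start + 1 nt).
    """
    if dialect == "tsv":
        return _read_gene_models_tsv(path)
    if dialect == "gff3":
        return _read_gene_models_gff3(path)
    raise ValueError(f"unknown dialect {dialect!r} (use 'gff3' or 'tsv')")


def _read_gene_models_tsv(path) -> list[GeneAnnotation]:
    out = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANN_COLS:
            raise ValueError(f"{path}: expected columns {_ANN_COLS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            gid, u5, cds, u3, memb, srp = parts
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            try:
                ann = GeneAnnotation(
                    gid, int(u5), int(cds), int(u3), memb in ("1", "True", "true"), srp
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(ann)
    return out


def _read_gene_models_gff3(path) -> list[GeneAnnotation]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises its own hierarchy
        raise ValueError(f"{path}: invalid GFF3 ({exc})") from exc

    lengths: dict[str, dict[str, int]] = defaultdict(lambda: {"five": 0, "cds": 0, "three": 0})
    labels: dict[str, tuple[bool, str]] = {}
    order: list[str] = []
    feature_map = {"five_prime_UTR": "five", "CDS": "cds", "three_prime_UTR": "three"}
    for gene in db.features_of_type("gene"):
        labels[gene.id] = (
            gene.attributes.get("membrane", ["0"])[0] in ("1", "True", "true"),
            gene.attributes.get("srp_class", ["unknown"])[0],
        )
        order.append(gene.id)
    for ftype, key in feature_map.items():
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent")
            if not parents:
                raise ValueError(f"{path}: {ftype} feature at {feat.start} without Parent")
            parent = parents[0]
            if parent not in lengths and parent not in order:
                order.append(parent)
            # GFF3 spans are 1-based inclusive: length = end - start + 1.
            # Lengths are orientation-free, so minus-strand genes need no
            # special casing here.
            lengths[parent][key] += feat.end - feat.start + 1
    out = []
    for gid in order:
        if gid not in lengths:
            continue  # gene line without region features: skip
        spans = lengths[gid]
        memb, srp = labels.get(gid, (False, "unknown"))
        try:
            ann = GeneAnnotation(gid, spans["five"], spans["cds"], spans["three"], memb, srp)
        except ValueError as exc:
            raise ValueError(f"{path}: gene {gid!r}: {exc}") from exc
        out.append(ann)
    if not out:
        raise ValueError(f"{path}: no gene models found")
    return out


# ---------------------------------------------------------------------------
# PARS scores


def write_pars_scores(profiles: Sequence[PARSProfile], path) -> None:
    """One gene per line: gene_id TAB semicolon-joined scores, NA = missing."""
    with open(path, "w") as fh:
        for prof in profiles:
            toks = ["NA" if math.isnan(v) else _FLOAT_FMT % v for v in prof.scores]
            fh.write(prof.gene_id + "\t" + ";".join(toks) + "\n")


def read_pars_scores(path) -> list[PARSProfile]:
    out = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: missing TAB separator")
            gid, rest = line.split("\t", 1)
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene line {gid!r}")
            seen.add(gid)
            toks = rest.split(";")
            if toks == [""]:
                raise ValueError(f"{path}:{lineno}: empty score list for {gid!r}")
            scores = np.empty(len(toks))
            for i, tok in enumerate(toks):
                if tok == "NA":
                    scores[i] = np.nan
                else:
                    try:
                        scores[i] = float(tok)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric score token {tok!r}"
                        )
            out.append(PARSProfile(gid, scores))
    return out


# ---------------------------------------------------------------------------
# codon coverage


def write_codon_coverage(coverages: Sequence[CodonCoverage], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsample_id\tcounts\n")
        for cov in coverages:
            fh.write(
                f"{cov.gene_id}\t{cov.sample_id}\t"
                + ";".join(str(int(v)) for v in cov.counts_per_codon)
                + "\n"
            )


def read_codon_coverage(path) -> list[CodonCoverage]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "sample_id", "counts"]:
            raise ValueError(f"{path}: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            gid, sid, toks = parts
            try:
                counts = np.array([int(t) for t in toks.split(";")], dtype=np.int64)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer codon count")
            out.append(CodonCoverage(gid, sid, counts))
    return out


# ---------------------------------------------------------------------------
# truth, TE results, rates


def write_truth(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttrue_class\ttrue_log2fc_mrna\ttrue_log2fc_te\tbase_mean\tdispersion\n")
        for t in truths:
            fh.write(
                "\t".join(
                    [
                        t.gene_id,
                        t.true_class,
                        _fmt(t.true_log2fc_mrna),
                        _fmt(t.true_log2fc_te),
                        _fmt(t.base_mean),
                        _fmt(t.dispersion),
                    ]
                )
                + "\n"
            )


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            str(r.gene_id),
            str(r.true_class),
            float(r.true_log2fc_mrna),
            float(r.true_log2fc_te),
            float(r.base_mean),
            float(r.dispersion),
        )
        for r in df.itertuples()
    ]


_TE_COLS = ["gene_id", "log2fc_mrna", "log2fc_rpf", "delta_te", "wald_z", "p", "fdr", "class_label"]


def write_te_results(results: Sequence[TEResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TE_COLS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        _fmt(r.log2fc_mrna),
                        _fmt(r.log2fc_rpf),
                        _fmt(r.delta_te),
                        _fmt(r.wald_z),
                        _fmt(r.p),
                        _fmt(r.fdr),
                        r.class_label,
                    ]
                )
                + "\n"
            )


def read_te_results(path) -> list[TEResult]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if list(df.columns) != _TE_COLS:
        raise ValueError(f"{path}: expected columns {_TE_COLS}")
    out = []
    for r in df.itertuples():
        out.append(
            TEResult(
                str(r.gene_id),
                float(r.log2fc_mrna) if pd.notna(r.log2fc_mrna) else float("nan"),
                float(r.log2fc_rpf) if pd.notna(r.log2fc_rpf) else float("nan"),
                float(r.delta_te) if pd.notna(r.delta_te) else float("nan"),
                float(r.wald_z) if pd.notna(r.wald_z) else float("nan"),
                float(r.p) if pd.notna(r.p) else float("nan"),
                float(r.fdr) if pd.notna(r.fdr) else float("nan"),
                str(r.class_label),
            )
        )
    return out


def write_rates(records: Sequence[RateRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcondition\tnTR\tcell_volume\tSR\tRA\tHL\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        r.condition,
                        _fmt(r.nTR),
                        _fmt(r.cell_volume),
                        _fmt(r.SR),
                        _fmt(r.RA),
                        _fmt(r.HL),
                    ]
                )
                + "\n"
            )


def read_rates(path) -> list[RateRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return [
        RateRecord(
            str(r.gene_id),
            str(r.condition),
            float(r.nTR),
            float(r.cell_volume),
            float(r.SR),
            float(r.RA),
            float(r.HL),
        )
        for r in df.itertuples()
    ]


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV dump of an arbitrary result frame (6 sig. digits)."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")
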