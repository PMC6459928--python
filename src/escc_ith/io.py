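"""Tabular readers/writers and newick tree I/O.

All tables are TSV with headers.  Mutation tables are MAF-like long
format (one row per mutation x sample); segment and SNP-BAF tables
are SEG-like; TCR tables follow AIRR-style column naming.  Numeric
round-trips are exact to 1e-9.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import pandas as pd

from .records import (
    Chain,
    Consequence,
    MutationRecord,
    ReadCounts,
    SampleMeta,
    SampleType,
    SegmentRecord,
    SnpBafRecord,
    TcrCloneRecord,
    VariantType,
)

MUTATION_COLUMNS = ["patient_id", "chrom", "pos", "ref", "alt", "variant_type",
                    "sample_id", "alt_reads", "ref_reads"]
OPTIONAL_MUTATION_COLUMNS = ["gene", "consequence", "sift", "polyphen",
                             "tri_context"]
SAMPLE_COLUMNS = ["patient_id", "sample_id", "sample_type", "purity", "ploidy",
                  "mean_depth"]


class FormatError(ValueError):
    pass


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing mandatory column(s) {missing}")


def _opt(row, col, cast=None):
    if col not in row or pd.isna(row[col]) or row[col] == "":
        return None
    return cast(row[col]) if cast else row[col]


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a long-format mutation table into grouped MutationRecords.

    One input row per (mutation, sample); rows of the same mutation are
    grouped into a single record keyed by (patient, chrom, pos, ref, alt).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    _require(df, MUTATION_COLUMNS, "mutation table")
    records: dict[tuple, MutationRecord] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            alt_reads, ref_reads = int(row["alt_reads"]), int(row["ref_reads"])
        except (TypeError, ValueError):
            raise FormatError(
                f"mutation table line {line_no}: non-integer read counts "
                f"({row['alt_reads']!r}, {row['ref_reads']!r})"
            ) from None
        key = (row["patient_id"], row["chrom"], int(row["pos"]), row["ref"],
               row["alt"])
        if key not in records:
            records[key] = MutationRecord(
                patient_id=row["patient_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                variant_type=VariantType(row["variant_type"]),
                gene=_opt(row, "gene"),
                consequence=Consequence(row["consequence"])
                if _opt(row, "consequence") else Consequence.OTHER,
                sift=_opt(row, "sift", float),
                polyphen=_opt(row, "polyphen", float),
                tri_context=_opt(row, "tri_context"),
            )
        records[key].per_sample_counts[row["sample_id"]] = ReadCounts(
            alt_reads, ref_reads
        )
    return list(records.values())


def write_mutation_table(records: list[MutationRecord], path) -> None:
    rows = []
    for rec in records:
        for sample_id, counts in sorted(rec.per_sample_counts.items()):
            rows.append({
                "patient_id": rec.patient_id, "chrom": rec.chrom,
                "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
                "variant_type": rec.variant_type.value,
                "gene": rec.gene or "",
                "consequence": rec.consequence.value,
                "sift": "" if rec.sift is None else rec.sift,
                "polyphen": "" if rec.polyphen is None else rec.polyphen,
                "tri_context": rec.tri_context or "",
                "sample_id": sample_id,
                "alt_reads": counts.alt, "ref_reads": counts.ref,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    _require(df, SAMPLE_COLUMNS, "sample table")
    out = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        purity = None if pd.isna(row["purity"]) else float(row["purity"])
        ploidy = None if pd.isna(row["ploidy"]) else float(row["ploidy"])
        out.append(SampleMeta(row["patient_id"], row["sample_id"],
                              SampleType(row["sample_type"]), purity, ploidy,
                              float(row["mean_depth"])))
    return out


def write_sample_table(metas: list[SampleMeta], path) -> None:
    rows = [{
        "patient_id": m.patient_id, "sample_id": m.sample_id,
        "sample_type": m.sample_type.value,
        "purity": "" if m.purity is None else m.purity,
        "ploidy": "" if m.ploidy is None else m.ploidy,
        "mean_depth": m.mean_depth,
    } for m in metas]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_segment_table(path) -> list[SegmentRecord]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["sample_id", "chrom", "start", "end", "log_r", "n_major",
                  "n_minor"], "segment table")
    return [SegmentRecord(r.sample_id, str(r.chrom), int(r.start), int(r.end),
                          float(r.log_r), int(r.n_major), int(r.n_minor))
            for r in df.itertuples(index=False)]


def write_segment_table(segments: list[SegmentRecord], path) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "log_r": s.log_r, "n_major": s.n_major,
        "n_minor": s.n_minor,
    } for s in segments]).to_csv(path, sep="\t", index=False)


def read_baf_table(path) -> list[SnpBafRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"phase_id": str})
    _require(df, ["sample_id", "chrom", "pos", "a_reads", "b_reads"],
             "SNP BAF table")
    out = []
    for r in df.itertuples(index=False):
        row = r._asdict()
        phase = row.get("phase_id")
        out.append(SnpBafRecord(row["sample_id"], str(row["chrom"]),
                                int(row["pos"]), int(row["a_reads"]),
                                int(row["b_reads"]),
                                None if pd.isna(phase) else phase))
    return out


def write_baf_table(snps: list[SnpBafRecord], path) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id, "chrom": s.chrom, "pos": s.pos,
        "a_reads": s.a_reads, "b_reads": s.b_reads,
        "phase_id": s.phase_id or "",
    } for s in snps]).to_csv(path, sep="\t", index=False)


TCR_COLUMNS = {"sample_id": "sample_id", "locus": "chain",
               "junction_aa": "cdr3_aa", "v_call": "v_gene",
               "j_call": "j_gene", "duplicate_count": "count",
               "productive": "productive"}


def read_tcr_table(path) -> list[TcrCloneRecord]:
    """AIRR-style clone table (locus, junction_aa, v_call, j_call,
    duplicate_count, productive)."""
    df = pd.read_csv(path, sep="\t")
    _require(df, list(TCR_COLUMNS), "TCR clone table")
    out = []
    for r in df.itertuples(index=False):
        row = r._asdict()
        out.append(TcrCloneRecord(
            row["sample_id"], Chain(row["locus"]), row["junction_aa"],
            row["v_call"], row["j_call"], int(row["duplicate_count"]),
            productive=bool(row["productive"]) if not isinstance(
                row["productive"], str)
            else row["productive"].strip().lower() in ("t", "true", "1"),
        ))
    return out


def write_tcr_table(records: list[TcrCloneRecord], path) -> None:
    pd.DataFrame([{
        "sample_id": r.sample_id, "locus": r.chain.value,
        "junction_aa": r.cdr3_aa, "v_call": r.v_gene, "j_call": r.j_gene,
        "duplicate_count": r.count, "productive": r.productive,
    } for r in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- newick

def write_newick(tree, path) -> None:
    """Write a tree (PhyloTree, skbio TreeNode, or newick string) to a file.

    Leaf labels must be unique; numeric lengths survive a round-trip
    through ``read_newick`` to 1e-9.
    """
    if hasattr(tree, "to_newick"):       # PhyloTree
        newick = tree.to_newick()
    elif hasattr(tree, "write"):         # skbio TreeNode
        buf = _io.StringIO()
        tree.write(buf, format="newick")
        newick = buf.getvalue().strip()
    else:
        newick = str(tree)
    try:
        parsed = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy rejects duplicate taxa itself
        if "Duplicate" in str(exc) or "duplicate" in str(exc):
            raise FormatError("duplicate leaf labels in tree") from exc
        raise
    labels = [leaf.taxon.label for leaf in parsed.leaf_node_iter()
              if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial leaf-set partitions of each edge (topology fingerprint)."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(leaves) < len(all_leaves):
            out.add(leaves)
    return out
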