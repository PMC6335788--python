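"""Readers and writers for the flat-file interfaces of the pipeline.

FASTA goes through Biopython, GFF3 through gffutils; tables are plain TSV
handled with pandas.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from bzipkit.domain_scanner import DomainAnnotation, BindingVariant, ProteinRecord
from bzipkit.intron_phase_mapper import GeneModel


def read_proteins(path) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records."""
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: dict[str, str], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_cds_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_gene_models(path) -> list[GeneModel]:
    """Parse CDS-bearing gene models from a GFF3 file.

    CDS features are grouped by their Parent (mRNA) feature; exon intervals
    are ordered in transcription order.  GFF3 phase columns are ignored —
    phases are recomputed from exon lengths downstream.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        exons = [(c.start, c.end) for c in cds]
        if mrna.strand == "-":
            exons = exons[::-1]
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        models.append(
            GeneModel(
                gene_id=gene_id,
                strand=mrna.strand,
                exons=exons,
                protein_id=mrna.id,
                chrom=mrna.seqid,
            )
        )
    return models


def annotations_to_frame(anns: list[DomainAnnotation]) -> pd.DataFrame:
    """Flatten domain annotations into the TSV scan-table layout."""
    rows = []
    for a in anns:
        rows.append(
            {
                "protein_id": a.protein_id,
                "anchor_n": a.anchor_n,
                "minus18": a.pos_minus18_residue,
                "minus10": a.pos_minus10_residue,
                "zipper_start": a.zipper_start,
                "basic_start": a.basic_span[0],
                "basic_end": a.basic_span[1],
                "hinge_start": a.hinge_span[0],
                "hinge_end": a.hinge_span[1],
                "zipper_end": a.zipper_span[1],
                "n_heptads": a.n_heptads,
                "variant_class": a.variant_class.value,
                "basic_truncated": a.basic_truncated,
            }
        )
    return pd.DataFrame(rows)


def frame_to_annotations(df: pd.DataFrame) -> list[DomainAnnotation]:
    anns = []
    for _, r in df.iterrows():
        anns.append(
            DomainAnnotation(
                protein_id=r["protein_id"],
                anchor_n=int(r["anchor_n"]),
                pos_minus18_residue=r["minus18"],
                pos_minus10_residue=r["minus10"],
                zipper_start=int(r["zipper_start"]),
                basic_span=(int(r["basic_start"]), int(r["basic_end"])),
                hinge_span=(int(r["hinge_start"]), int(r["hinge_end"])),
                zipper_span=(int(r["zipper_start"]), int(r["zipper_end"])),
                n_heptads=int(r["n_heptads"]),
                variant_class=BindingVariant(r["variant_class"]),
                basic_truncated=bool(r["basic_truncated"]),
            )
        )
    return anns


def read_gene_order(path) -> dict[str, list[str]]:
    """Read a TSV with columns ``chrom`` and ``gene`` (chromosome order)."""
    df = pd.read_csv(path, sep="\t")
    return {
        chrom: sub["gene"].tolist() for chrom, sub in df.groupby("chrom", sort=False)
    }


def read_similarity_edges(path) -> list[tuple[str, str, float]]:
    """Read a TSV with columns ``gene_a``, ``gene_b``, ``evalue``."""
    df = pd.read_csv(path, sep="\t")
    return list(df[["gene_a", "gene_b", "evalue"]].itertuples(index=False, name=None))


def read_pair_list(path) -> list[tuple[str, str]]:
    """Read a precomputed duplicated-pair TSV (columns ``gene_a``, ``gene_b``)."""
    df = pd.read_csv(path, sep="\t")
    return list(df[["gene_a", "gene_b"]].itertuples(index=False, name=None))


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
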