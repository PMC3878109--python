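"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython, VCF 4.2 via pysam, GFF3 read via gffutils (written as
standard 9-column lines — gffutils has no writer), tabular data as TSV via
pandas. Fixture bundles are written atomically: everything is staged in a
temporary sibling directory that is renamed into place only once complete.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_vcf",
    "read_vcf",
    "write_bundle",
    "read_bundle",
]


def write_fasta(reference: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models (gene_id, chrom, start, end) as GFF3 gene features.

    Coordinates are 1-based closed, per the GFF3 standard.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']};Name={g['gene_id']}"
            fh.write(
                f"{g['chrom']}\thybase\tgene\t{int(g['start'])}\t{int(g['end'])}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene features back into a (gene_id, chrom, start, end, length) table."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        rows.append(
            (feat.id, feat.seqid, feat.start, feat.end, feat.end - feat.start + 1)
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "length"])


def write_vcf(
    snps: pd.DataFrame,
    path,
    parents: list[str],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a parental SNP table as VCF 4.2 with per-parent genotypes.

    *snps* needs columns chrom, pos, ref, alt and one ``gt_<parent>`` column
    (values "RR"/"AA") per parent; optional ``gene_id`` and ``posterior``
    become INFO fields.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "hybase")
    if contigs:
        for name, length in contigs.items():
            header.contigs.add(name, length=length)
    else:
        for name in pd.unique(snps["chrom"]):
            header.contigs.add(str(name))
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"), ("Description", "Gene id")]
    )
    header.add_meta(
        "INFO",
        items=[("ID", "GP"), ("Number", "1"), ("Type", "Float"), ("Description", "Genotype posterior")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    for par in parents:
        header.add_sample(par)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in snps.iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,  # pysam is 0-based internally
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
            )
            if "gene_id" in snps.columns:
                rec.info["GENE"] = str(row["gene_id"])
            if "posterior" in snps.columns:
                rec.info["GP"] = float(row["posterior"])
            for par in parents:
                gt = row[f"gt_{par}"]
                rec.samples[par]["GT"] = (0, 0) if gt == "RR" else (1, 1)
            vcf.write(rec)


def read_vcf(path) -> pd.DataFrame:
    """Read a hybase VCF back into the tabular SNP representation."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,  # 1-based
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else None,
                "gene_id": rec.info.get("GENE"),
            }
            for s in samples:
                gt = rec.samples[s]["GT"]
                row[f"gt_{s}"] = "RR" if gt == (0, 0) else ("AA" if gt == (1, 1) else "RA")
            rows.append(row)
    df = pd.DataFrame(rows)
    if "gene_id" in df.columns and df["gene_id"].isna().all():
        df = df.drop(columns=["gene_id"])
    return df


_BUNDLE_FILES = {
    "reference": "reference.fasta",
    "genes": "genes.gff3",
    "snps": "snps.vcf",
    "parent_counts": "parent_counts.tsv",
    "truth": "truth.tsv",
    "phenotypes": "phenotypes.tsv",
    "manifest": "manifest.json",
}


def write_bundle(parents, f1_counts: dict[str, pd.DataFrame], phenotypes, outdir) -> dict:
    """Write a complete fixture bundle atomically; return the manifest.

    See :func:`hybase.simulate.write_fixture_bundle` for the file list.
    Raises if *outdir* already exists (bundles are immutable).
    """
    outdir = Path(outdir)
    if outdir.exists():
        raise FileExistsError(f"bundle directory {outdir} already exists")
    outdir.parent.mkdir(parents=True, exist_ok=True)
    stage = Path(tempfile.mkdtemp(prefix=f".{outdir.name}.", dir=outdir.parent))
    try:
        write_fasta(parents.reference, stage / _BUNDLE_FILES["reference"])
        write_gff3(parents.genes, stage / _BUNDLE_FILES["genes"])
        contigs = {c: len(s) for c, s in parents.reference.items()}
        write_vcf(
            parents.snps,
            stage / _BUNDLE_FILES["snps"],
            parents=list(parents.config.parents),
            contigs=contigs,
        )
        parents.expression.to_csv(stage / _BUNDLE_FILES["parent_counts"], sep="\t", index=False)
        parents.truth.to_csv(stage / _BUNDLE_FILES["truth"], sep="\t", index=False)
        phenotypes.to_csv(stage / _BUNDLE_FILES["phenotypes"], sep="\t", index=False)
        for cross_id, table in f1_counts.items():
            table.to_csv(stage / f"f1_counts_{cross_id}.tsv", sep="\t", index=False)
        manifest = {
            "config": parents.config.to_dict(),
            "config_hash": parents.config.config_hash(),
            "seed": parents.config.seed,
            "crosses": sorted(f1_counts),
            "files": sorted(
                [*(_BUNDLE_FILES.values()), *(f"f1_counts_{c}.tsv" for c in f1_counts)]
            ),
        }
        with open(stage / _BUNDLE_FILES["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        stage.rename(outdir)
    except Exception:
        shutil.rmtree(stage, ignore_errors=True)
        raise
    return manifest


def read_bundle(bundle_dir):
    """Read a fixture bundle back; returns (manifest, tables dict)."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / _BUNDLE_FILES["manifest"]) as fh:
        manifest = json.load(fh)
    tables = {
        "reference": read_fasta(bundle_dir / _BUNDLE_FILES["reference"]),
        "genes": read_gff3(bundle_dir / _BUNDLE_FILES["genes"]),
        "snps": read_vcf(bundle_dir / _BUNDLE_FILES["snps"]),
        "parent_counts": pd.read_csv(bundle_dir / _BUNDLE_FILES["parent_counts"], sep="\t"),
        "truth": pd.read_csv(
            bundle_dir / _BUNDLE_FILES["truth"],
            sep="\t",
            keep_default_na=False,
            dtype={"silent_parent": str, "gdm_source": str},
        ),
        "phenotypes": pd.read_csv(bundle_dir / _BUNDLE_FILES["phenotypes"], sep="\t"),
        "f1_counts": {
            c: pd.read_csv(bundle_dir / f"f1_counts_{c}.tsv", sep="\t")
            for c in manifest["crosses"]
        },
    }
    return manifest, tables
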