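"""Readers, writers and validated in-memory containers for every file the
pipeline touches.

Conventions enforced here, once, at the parser boundary:

* internal genomic coordinates are 0-based half-open everywhere;
* VCF ``POS`` is 1-based (converted on read/write);
* BED intervals are 0-based half-open (no conversion needed);
* matrices are TSV with a mandatory header row, transcripts/genes in rows
  and samples in columns; gzip is handled transparently by pandas.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A file violated the expected schema; message names file and rule."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """Transcript-level abundances, transcripts x samples.

    ``tpm`` is the modeled quantity downstream; ``counts`` (estimated counts,
    same shape) is carried along when available.
    """

    tpm: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.tpm.index.duplicated().any():
            dup = self.tpm.index[self.tpm.index.duplicated()][0]
            raise SchemaError(f"duplicate transcript id: {dup!r}")
        if self.tpm.columns.duplicated().any():
            dup = self.tpm.columns[self.tpm.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample id: {dup!r}")
        vals = self.tpm.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise SchemaError("expression values must be finite and >= 0")
        if self.counts is not None and self.counts.shape != self.tpm.shape:
            raise SchemaError("counts and tpm shapes differ")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


METADATA_COLUMNS = [
    "patient_id",
    "response",
    "tissue_state",
    "sex",
    "age_at_diagnosis",
    "corticosteroid_use",
    "azathioprine_use",
    "aminosalicylate_use",
]

#: binary covariate/label columns; response is 1 = responder at week 12
BINARY_COLUMNS = [
    "response",
    "sex",
    "corticosteroid_use",
    "azathioprine_use",
    "aminosalicylate_use",
]


def validate_metadata(meta: pd.DataFrame, *, source: str = "<memory>") -> pd.DataFrame:
    """Check a sample/patient metadata table (indexed by sample_id)."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns and c != "tissue_state"]
    if missing:
        raise SchemaError(f"{source}: missing metadata columns {missing}")
    if meta.index.duplicated().any():
        raise SchemaError(f"{source}: duplicate sample id {meta.index[meta.index.duplicated()][0]!r}")
    for col in BINARY_COLUMNS:
        if col in meta.columns and not meta[col].isin([0, 1]).all():
            raise SchemaError(f"{source}: column {col!r} must be binary 0/1")
    if "tissue_state" in meta.columns:
        ok = meta["tissue_state"].isin(["healthy", "inflamed"])
        if not ok.all():
            bad = meta.loc[~ok, "tissue_state"].iloc[0]
            raise SchemaError(f"{source}: tissue_state must be healthy/inflamed, got {bad!r}")
    return meta


@dataclasses.dataclass
class GenotypeMatrix:
    """Dosage-coded biallelic variants, patients x variants.

    Dosage counts the ALT allele (0/1/2); missing genotypes are NaN.
    ``variants`` has columns chrom, pos (1-based), id, ref, alt indexed by id.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.variants.index.duplicated().any():
            dup = self.variants.index[self.variants.index.duplicated()][0]
            raise SchemaError(f"duplicate variant id: {dup!r}")
        if list(self.dosages.columns) != list(self.variants.index):
            raise SchemaError("dosage columns do not match variant table")
        if (self.variants["pos"] < 1).any():
            raise SchemaError("VCF POS must be >= 1")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0])
        if not ok.all():
            raise SchemaError("dosages must be 0/1/2 or missing")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def minor_allele_orientation(self) -> pd.Series:
        """Cohort-wide indicator: True where the ALT allele is the minor one.

        Minor-allele dosage is ``d`` where True and ``2 - d`` where False;
        association betas and allele frequencies are reported on this scale.
        """
        af = self.dosages.mean(axis=0) / 2.0
        return af <= 0.5


@dataclasses.dataclass
class GeneModel:
    """Gene coordinates (0-based half-open) plus the transcript->gene map."""

    genes: pd.DataFrame           # index gene_id; columns chrom, start, end
    tx2gene: pd.Series            # index transcript_id -> gene_id

    def __post_init__(self) -> None:
        if (self.genes["start"] >= self.genes["end"]).any():
            bad = self.genes.index[self.genes["start"] >= self.genes["end"]][0]
            raise SchemaError(f"gene {bad!r}: start must be < end")
        if self.tx2gene.index.duplicated().any():
            dup = self.tx2gene.index[self.tx2gene.index.duplicated()][0]
            raise SchemaError(f"transcript {dup!r} maps to more than one gene")
        unknown = set(self.tx2gene) - set(self.genes.index)
        if unknown:
            raise SchemaError(f"transcript map references unknown genes: {sorted(unknown)[:5]}")

    def transcripts_of(self, gene_id: str) -> list[str]:
        return list(self.tx2gene.index[self.tx2gene == gene_id])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate {what} id {dup!r}")
    return df


def read_expression(path: str | Path, counts_path: str | Path | None = None) -> ExpressionMatrix:
    tpm = _read_tsv_matrix(path, "transcript")
    counts = _read_tsv_matrix(counts_path, "transcript") if counts_path else None
    try:
        return ExpressionMatrix(tpm=tpm, counts=counts)
    except SchemaError as e:
        raise SchemaError(f"{path}: {e}") from None


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(meta, source=str(path))


def check_sample_alignment(expr: ExpressionMatrix, meta: pd.DataFrame) -> None:
    """Expression samples and metadata rows must agree exactly."""
    e, m = set(expr.sample_ids), set(meta.index)
    if e != m:
        only_e, only_m = sorted(e - m), sorted(m - e)
        raise SchemaError(
            f"sample mismatch: {only_e[:5]} only in expression, {only_m[:5]} only in metadata"
        )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a VCF v4.2 into a dosage matrix; multi-allelic records rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise SchemaError(f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}")
        rows.append((rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}", rec.REF, rec.ALT[0]))
        # gt_types: 0=hom-ref,1=het,2=unknown,3=hom-alt
        gt = rec.gt_types.astype(float)
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        dosage_rows.append(d)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"]).set_index(
        "id", drop=False
    )
    variants.index.name = None
    dosages = pd.DataFrame(
        np.array(dosage_rows).T if dosage_rows else np.empty((len(samples), 0)),
        index=samples,
        columns=variants.index,
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


def write_vcf(path: str | Path, gm: GenotypeMatrix) -> None:
    """Write dosages as unphased GTs (VCF v4.2, biallelic SNVs)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = list(dict.fromkeys(gm.variants["chrom"]))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.patient_ids) + "\n")
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        D = gm.dosages.to_numpy(dtype=float)
        for j, (vid, row) in enumerate(gm.variants.iterrows()):
            gts = "\t".join(
                "./." if np.isnan(D[i, j]) else gt_of[D[i, j]] for i in range(D.shape[0])
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_gene_bed(bed_path: str | Path, map_path: str | Path) -> GeneModel:
    """BED6 gene intervals + transcript->gene TSV (columns transcript_id, gene_id)."""
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    genes = bed.set_index("gene_id")[["chrom", "start", "end"]]
    genes.index.name = None
    if genes.index.duplicated().any():
        raise SchemaError(f"{bed_path}: duplicate gene id")
    tmap = pd.read_csv(map_path, sep="\t")
    if not {"transcript_id", "gene_id"} <= set(tmap.columns):
        raise SchemaError(f"{map_path}: need columns transcript_id, gene_id")
    tx2gene = tmap.set_index("transcript_id")["gene_id"]
    tx2gene.index.name = None
    return GeneModel(genes=genes, tx2gene=tx2gene)


def write_gene_bed(path: str | Path, model: GeneModel) -> None:
    with open(path, "w") as fh:
        for gid, row in model.genes.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{gid}\t0\t+\n")


def write_tx2gene(path: str | Path, model: GeneModel) -> None:
    df = model.tx2gene.rename("gene_id").rename_axis("transcript_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_go(path: str | Path) -> pd.DataFrame:
    """Term->gene annotation: columns term_id, namespace in {BP,CC,MF}, gene_id."""
    go = pd.read_csv(path, sep="\t")
    need = {"term_id", "namespace", "gene_id"}
    if not need <= set(go.columns):
        raise SchemaError(f"{path}: need columns {sorted(need)}")
    bad = ~go["namespace"].isin(["BP", "CC", "MF"])
    if bad.any():
        raise SchemaError(f"{path}: namespace must be BP/CC/MF, got {go.loc[bad, 'namespace'].iloc[0]!r}")
    return go


def read_signature(path: str | Path) -> pd.DataFrame:
    """Signature matrix, signature genes x cell types; entries must be >= 0."""
    sig = _read_tsv_matrix(path, "signature gene")
    if (sig.to_numpy() < 0).any():
        raise SchemaError(f"{path}: signature entries must be non-negative")
    return sig


def read_edges(path: str | Path) -> pd.DataFrame:
    """Undirected interaction edge list; deduplicated, self-loops dropped."""
    e = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"} <= set(e.columns):
        raise SchemaError(f"{path}: need columns gene_a, gene_b")
    e = e[e["gene_a"] != e["gene_b"]].copy()
    key = e.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    e = e.loc[~key.duplicated()].reset_index(drop=True)
    return e


def write_matrix(path: str | Path, df: pd.DataFrame, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
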