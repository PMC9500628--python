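"""End-to-end orchestration: simulate (or load) -> deconvolve -> DE (four
approaches x two strata) -> meta-combination -> GO enrichment -> candidate
union -> window GWAS with Meff adjustment and LD pruning -> eQTL scan ->
random-forest validation -> final candidate-locus table.

Every stage reads and writes plain text files under one output directory
and records input/output SHA-256 hashes, parameters and warnings in a JSON
run manifest, so a run can be verified and resumed mid-way.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, de, deconvolution, enrichment, eqtl, io, simulate

logger = logging.getLogger(__name__)

STAGES = ["simulate", "deconvolve", "de", "meta", "enrich", "gwas", "eqtl", "validate", "final"]


@dataclasses.dataclass
class Thresholds:
    de_p: float = 0.05
    de_p_strict: float = 0.005
    lfc: float = 2.0
    go_p: float = 0.01
    go_q: float = 0.05
    assoc_q: float = 0.05
    eqtl_p: float = 0.05
    r2_max: float = 0.5
    flank: int = 100_000

    def __post_init__(self) -> None:
        for name in ("de_p", "de_p_strict", "go_p", "go_q", "assoc_q", "eqtl_p", "r2_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"threshold {name}={v} must be in (0,1)")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    design: dict = dataclasses.field(default_factory=dict)
    expression_params: dict = dataclasses.field(default_factory=dict)
    ld_profile: dict = dataclasses.field(default_factory=dict)
    effect_params: dict = dataclasses.field(default_factory=dict)
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    approaches: list[str] = dataclasses.field(default_factory=lambda: list(de.APPROACHES))
    skip_go: bool = False
    validation_mode: str = "oob"
    n_trees: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)


def _read_meta(path: Path) -> pd.DataFrame:
    """Meta-DEI tables carry a literal class label "null"; keep pandas from
    parsing it as missing."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner with a hash-checked manifest."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "run.manifest.json"
        self.manifest: dict = {"stages": {}, "config": dataclasses.asdict(config)}

    # -- manifest -----------------------------------------------------------
    def _record(self, stage: str, inputs: list[Path], outputs: list[Path], params: dict) -> None:
        self.manifest["stages"][stage] = {
            "inputs": {str(p): _hash_file(p) for p in inputs if p.exists()},
            "outputs": {str(p): _hash_file(p) for p in outputs},
            "params": params,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        }
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)

    def _verify_upstream(self, from_stage: str) -> None:
        with open(self.manifest_path) as fh:
            self.manifest = json.load(fh)
        idx = STAGES.index(from_stage)
        for st in STAGES[:idx]:
            rec = self.manifest["stages"].get(st)
            if rec is None:
                raise ValueError(f"cannot resume from {from_stage}: stage {st} never ran")
            for path, digest in rec["outputs"].items():
                p = Path(path)
                if not p.exists() or _hash_file(p) != digest:
                    raise ValueError(f"hash mismatch for {path}; upstream output changed")

    # -- stages -------------------------------------------------------------
    def stage_simulate(self) -> None:
        design = simulate.CohortDesign(seed=self.cfg.seed, **self.cfg.design)
        cohort = simulate.generate_cohort(
            design,
            expr_params=simulate.ExpressionParams(**self.cfg.expression_params),
            ld_profile=simulate.LDProfile(**self.cfg.ld_profile),
            effect_params=simulate.VariantEffectParams(**self.cfg.effect_params),
        )
        paths = simulate.write_cohort(cohort, self.out / "inputs")
        truth_dir = self.out / "truth"
        truth_dir.mkdir(exist_ok=True)
        cohort.truth.planted_dei.to_csv(truth_dir / "planted_dei.tsv", sep="\t", index=False)
        cohort.truth.planted_variants.to_csv(truth_dir / "planted_variants.tsv", sep="\t", index=False)
        cohort.truth.eqtl_pairs.to_csv(truth_dir / "eqtl_pairs.tsv", sep="\t", index=False)
        cohort.truth.true_fractions.to_csv(truth_dir / "true_fractions.tsv", sep="\t", index_label="sample_id")
        self._record(
            "simulate", [], [Path(p) for p in paths.values()],
            {"seed": self.cfg.seed, "design": dataclasses.asdict(design)},
        )

    def _inputs(self) -> dict:
        d = self.out / "inputs"
        expr = io.read_expression(d / "expression_tpm.tsv", d / "expression_counts.tsv")
        smeta = io.read_metadata(d / "samples.tsv")
        io.check_sample_alignment(expr, smeta)
        pmeta = pd.read_csv(d / "patients.tsv", sep="\t", index_col=0)
        gm = io.read_vcf(d / "cohort.vcf")
        genes = io.read_gene_bed(d / "genes.bed", d / "tx2gene.tsv")
        go = io.read_go(d / "go.tsv")
        sig = io.read_signature(d / "signature.tsv")
        edges = io.read_edges(d / "edges.tsv")
        return dict(expr=expr, smeta=smeta, pmeta=pmeta, gm=gm, genes=genes, go=go, sig=sig, edges=edges)

    def stage_deconvolve(self) -> None:
        x = self._inputs()
        frac = deconvolution.run_deconvolution(
            x["expr"], x["genes"], x["sig"], simulate.AGGREGATION_MAP
        )
        out = self.out / "fractions.tsv"
        frac.to_csv(out, sep="\t", index_label="sample_id")
        self._record("deconvolve", [self.out / "inputs" / "expression_tpm.tsv"], [out], {})

    def stage_de(self) -> None:
        x = self._inputs()
        frac = pd.read_csv(self.out / "fractions.tsv", sep="\t", index_col=0)
        outs = []
        for approach in self.cfg.approaches:
            for stratum in ("healthy", "inflamed"):
                tab = de.run_approach(x["expr"], x["smeta"], frac, approach, stratum)
                p = self.out / f"de_{approach}_{stratum}.tsv"
                tab.to_csv(p, sep="\t", index=False)
                outs.append(p)
                logger.info("de %s/%s: %d transcripts", approach, stratum, len(tab))
        self._record("de", [self.out / "fractions.tsv"], outs, {"approaches": self.cfg.approaches})

    def stage_meta(self) -> None:
        outs = []
        for approach in self.cfg.approaches:
            h = pd.read_csv(self.out / f"de_{approach}_healthy.tsv", sep="\t", index_col="transcript_id")
            h["transcript_id"] = h.index
            i = pd.read_csv(self.out / f"de_{approach}_inflamed.tsv", sep="\t", index_col="transcript_id")
            i["transcript_id"] = i.index
            p_th = self.cfg.thresholds.de_p_strict if approach == "III" else self.cfg.thresholds.de_p
            m = de.meta_combine(h, i, approach, p_thresh=p_th, lfc_thresh=self.cfg.thresholds.lfc)
            p = self.out / f"meta_{approach}.tsv"
            m.to_csv(p, sep="\t", index=False)
            outs.append(p)
            counts = m["class"].value_counts()
            logger.info("meta %s: %s", approach, counts.to_dict())
        self._record("meta", [], outs, {})

    def stage_enrich(self) -> None:
        x = self._inputs()
        tx2gene = x["genes"].tx2gene
        th = enrichment.EnrichmentThresholds(
            p_max=self.cfg.thresholds.go_p, q_max=self.cfg.thresholds.go_q
        )
        # universe: genes with >= 1 transcript passing the DE expression
        # filter in either stratum
        smeta = x["smeta"]
        kept_tx = set()
        for stratum in ("healthy", "inflamed"):
            sel = smeta.index[smeta["tissue_state"] == stratum]
            kept_tx |= set(de.expression_filter(x["expr"].tpm[sel]))
        universe = set(tx2gene.reindex(sorted(kept_tx)).dropna())
        runs = []
        for approach in self.cfg.approaches:
            m = _read_meta(self.out / f"meta_{approach}.tsv").set_index("transcript_id", drop=False).rename_axis(None)
            for cls in ("consistent", "opposite"):
                genes_set = enrichment.dei_genes_for_run(m, tx2gene, cls) & universe
                res = enrichment.enrich(genes_set, x["go"], universe, th, run=f"{approach}_{cls}")
                runs.append(res)
        allres = pd.concat(runs, ignore_index=True)
        p_enrich = self.out / "enrichment.tsv"
        allres.to_csv(p_enrich, sep="\t", index=False)
        if self.cfg.skip_go:
            candidates = sorted(universe)
        else:
            candidates = sorted(enrichment.candidate_union(runs))
        p_cand = self.out / "candidate_genes.txt"
        p_cand.write_text("\n".join(candidates) + ("\n" if candidates else ""))
        logger.info("enrich: %d significant terms, %d candidate genes", len(allres), len(candidates))
        self._record("enrich", [], [p_enrich, p_cand], {"skip_go": self.cfg.skip_go})

    def stage_gwas(self) -> None:
        x = self._inputs()
        candidates = [
            g for g in (self.out / "candidate_genes.txt").read_text().split() if g
        ]
        tab = assoc.run_gwas(
            x["gm"], x["pmeta"], candidates, x["genes"].genes,
            flank=self.cfg.thresholds.flank,
            q_max=self.cfg.thresholds.assoc_q,
            r2_max=self.cfg.thresholds.r2_max,
        )
        p = self.out / "assoc.tsv"
        tab.to_csv(p, sep="\t", index=False)
        n_sig = int(tab["significant"].sum()) if len(tab) else 0
        logger.info("gwas: %d signals in %d loci", n_sig, tab.loc[tab["significant"], "locus"].nunique() if len(tab) else 0)
        self._record("gwas", [self.out / "candidate_genes.txt"], [p], {})

    def stage_eqtl(self) -> None:
        x = self._inputs()
        tab = pd.read_csv(self.out / "assoc.tsv", sep="\t")
        hits = tab[tab["significant"] & tab["independent"]]
        tx2gene = x["genes"].tx2gene
        meta_tx = set()
        for approach in self.cfg.approaches:
            m = _read_meta(self.out / f"meta_{approach}.tsv")
            meta_tx |= set(m.loc[m["class"] != "null", "transcript_id"])
        pairs = []
        for _, row in hits.iterrows():
            gene = row["locus"]
            for tx in tx2gene.index[tx2gene == gene]:
                if tx in meta_tx:
                    pairs.append({"gene_id": gene, "transcript_id": tx, "variant_id": row["variant_id"]})
        pairs_df = pd.DataFrame(pairs, columns=["gene_id", "transcript_id", "variant_id"])
        res = (
            eqtl.eqtl_scan(pairs_df, x["expr"], x["gm"], x["smeta"], p_max=self.cfg.thresholds.eqtl_p)
            if len(pairs_df)
            else pd.DataFrame(columns=["gene_id", "transcript_id", "variant_id", "H", "p_all", "p_healthy", "p_inflamed", "significant"])
        )
        p = self.out / "eqtl.tsv"
        res.to_csv(p, sep="\t", index=False)
        self._record("eqtl", [self.out / "assoc.tsv"], [p], {})

    def stage_validate(self) -> None:
        x = self._inputs()
        res_eqtl = pd.read_csv(self.out / "eqtl.tsv", sep="\t")
        tab = pd.read_csv(self.out / "assoc.tsv", sep="\t")
        rows = []
        prob_frames = []
        smeta = x["smeta"]
        labels = smeta["response"].astype(int)
        tissue = (smeta["tissue_state"] == "inflamed").astype(float)
        sel_tx = sorted(set(res_eqtl["transcript_id"])) if len(res_eqtl) else []
        if sel_tx:
            feats = np.log2(x["expr"].tpm.loc[sel_tx].T + 1.0)
            feats["tissue_state"] = tissue
            vr = eqtl.random_forest_validate(
                feats, labels, seed=self.cfg.seed, n_trees=self.cfg.n_trees,
                mode=self.cfg.validation_mode, feature_set="selected_transcripts",
            )
            rows.append(vr)
        sel_var = sorted(set(res_eqtl.loc[res_eqtl["significant"], "variant_id"])) if len(res_eqtl) else []
        if not sel_var and len(tab):
            sel_var = sorted(set(tab.loc[tab["significant"] & tab["independent"], "variant_id"]))
        if sel_var:
            pmeta = x["pmeta"]
            dfeat = x["gm"].dosages[sel_var].fillna(x["gm"].dosages[sel_var].mean())
            vr = eqtl.random_forest_validate(
                dfeat, pmeta["response"].astype(int), seed=self.cfg.seed,
                n_trees=self.cfg.n_trees, mode=self.cfg.validation_mode,
                feature_set="eqtl_variants",
            )
            rows.append(vr)
        out = pd.DataFrame(
            [
                {
                    "feature_set": r.feature_set,
                    "mode": r.mode,
                    "auc": r.auc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "n_features": len(r.probabilities),
                }
                for r in rows
            ],
            columns=["feature_set", "mode", "auc", "ci_low", "ci_high", "n_features"],
        )
        p = self.out / "validation.tsv"
        out.to_csv(p, sep="\t", index=False)
        for r in rows:
            prob_frames.append(r.probabilities.rename(r.feature_set))
        if prob_frames:
            pd.concat(prob_frames, axis=1).to_csv(self.out / "validation_probabilities.tsv", sep="\t", index_label="id")
        self._record("validate", [self.out / "eqtl.tsv"], [p], {"mode": self.cfg.validation_mode})

    def stage_final(self) -> None:
        x = self._inputs()
        tab = pd.read_csv(self.out / "assoc.tsv", sep="\t")
        res_eqtl = pd.read_csv(self.out / "eqtl.tsv", sep="\t")
        val = pd.read_csv(self.out / "validation.tsv", sep="\t")
        hits = tab[tab["significant"] & tab["independent"]]
        rows = []
        for gene, grp in hits.groupby("locus"):
            e = res_eqtl[res_eqtl["gene_id"] == gene] if "gene_id" in res_eqtl.columns else res_eqtl.iloc[0:0]
            rows.append(
                {
                    "gene_id": gene,
                    "transcripts": ",".join(sorted(set(e["transcript_id"]))) if len(e) else "",
                    "independent_variants": ",".join(sorted(set(grp["variant_id"]))),
                    "n_signals": int(tab[(tab["locus"] == gene) & tab["significant"]].shape[0]),
                    "n_eqtl_significant": int(e["significant"].sum()) if len(e) else 0,
                    "transcript_auc": float(val.loc[val["feature_set"] == "selected_transcripts", "auc"].iloc[0]) if (val["feature_set"] == "selected_transcripts").any() else np.nan,
                    "variant_auc": float(val.loc[val["feature_set"] == "eqtl_variants", "auc"].iloc[0]) if (val["feature_set"] == "eqtl_variants").any() else np.nan,
                }
            )
        final = pd.DataFrame(
            rows,
            columns=[
                "gene_id", "transcripts", "independent_variants", "n_signals",
                "n_eqtl_significant", "transcript_auc", "variant_auc",
            ],
        ).sort_values("gene_id") if rows else pd.DataFrame(
            columns=[
                "gene_id", "transcripts", "independent_variants", "n_signals",
                "n_eqtl_significant", "transcript_auc", "variant_auc",
            ]
        )
        p = self.out / "candidate_loci.tsv"
        final.to_csv(p, sep="\t", index=False)
        logger.info("final: %d candidate loci", len(final))
        self._record("final", [self.out / "assoc.tsv"], [p], {})

    # -- drivers ------------------------------------------------------------
    def run_all(self) -> pd.DataFrame:
        for st in STAGES:
            logger.info("stage %s", st)
            getattr(self, f"stage_{st}")()
        return pd.read_csv(self.out / "candidate_loci.tsv", sep="\t")

    def resume(self, from_stage: str) -> pd.DataFrame:
        if from_stage not in STAGES:
            raise ValueError(f"unknown stage {from_stage!r}")
        self._verify_upstream(from_stage)
        for st in STAGES[STAGES.index(from_stage):]:
            logger.info("stage %s (resumed)", st)
            getattr(self, f"stage_{st}")()
        return pd.read_csv(self.out / "candidate_loci.tsv", sep="\t")


def run_all(config: PipelineConfig) -> pd.DataFrame:
    """Run the complete pipeline; returns the final candidate-locus table."""
    return Pipeline(config).run_all()
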