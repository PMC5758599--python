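"""End-to-end orchestration: simulate -> measure -> EFD/PH -> PCA ->
REML adjust -> phenomic stats -> genomics.

A run is driven by a single :class:`RunConfig` (loadable from YAML).  Each
stage writes CSV outputs into the run directory and records a content hash
in the run manifest; re-running with an unchanged config and inputs skips
stages whose outputs are already up to date.

The synthetic world is genetically grounded: accession breeding values for
the log aspect ratio are generated from simulated genotypes at a configured
heritability, leaves are grown from those aspect ratios, and the genomics
stage then re-estimates heritability and prediction accuracy from the
measured, position-adjusted phenotypes — closing the loop from genotype to
silhouette and back.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from leafscape import __version__
from leafscape.errors import LeafscapeError, ParameterError

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Validated configuration of a full synthetic run."""

    out_dir: str = "leafscape_run"
    seed: int = 0
    # population
    n_accessions: int = 100
    leaves_per_tree: tuple = (8, 10)
    mean_log_aspect: float = math.log(1.8)
    sd_log_aspect: float = 0.22
    blade_scale_px: float = 300.0
    scale_cm_per_px: float = 1.0 / 118.11
    # orchard; variances are on the standardized (unit-variance) trait scale
    n_rgrid: int = 5
    n_cgrid: int = 5
    var_r: float = 0.10
    var_c: float = 0.10
    var_rc: float = 0.05
    var_resid: float = 0.05
    # descriptors
    efd_harmonics: int = 20
    ph_rings: int = 16
    ph_levels: int = 500
    ph_bandwidth: float = 0.05
    ph_r_max: float = 2.5
    n_pcs_keep: int = 5
    # genetics
    n_snps: int = 2000
    n_causal: int = 200
    h2_true: float = 0.6
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 10
    gwas_pcs: int = 3
    cv_folds: int = 5
    cv_reps: int = 3
    write_images: bool = False

    def validate(self) -> None:
        if self.n_accessions < 10:
            raise ParameterError("need at least 10 accessions")
        if not 0 <= self.h2_true <= 1:
            raise ParameterError("h2_true must be in [0, 1]")
        if self.seed < 0:
            raise ParameterError("seed must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.leaves_per_tree, list):
            cfg.leaves_per_tree = tuple(cfg.leaves_per_tree)
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    """Traceability record: config snapshot, stage hashes, timestamps."""

    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "version": self.version, "stages": self.stages},
                fh,
                indent=2,
                default=str,
            )

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(config=raw["config"], version=raw["version"], stages=raw["stages"])


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _stage_key(name: str, cfg_dict: dict, input_hashes: list) -> str:
    payload = json.dumps([name, cfg_dict, input_hashes], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, force: bool = False) -> RunManifest:
    """Execute all stages in dependency order with output caching."""
    from leafscape import efd as efd_mod
    from leafscape import genomics as gen
    from leafscape import morphostats as ms
    from leafscape import ph as ph_mod
    from leafscape import reml
    from leafscape import synthetic as syn
    from leafscape.measure import extract_contour, linear_traits, summarize_tree

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    manifest_path = out / "manifest.json"
    old = RunManifest.load(manifest_path) if manifest_path.exists() and not force else None
    manifest = RunManifest(config=cfg_dict, version=__version__)

    def fresh(stage: str, outputs: list[Path], input_hashes: list) -> bool:
        """True when the cached outputs of a stage are still valid."""
        key = _stage_key(stage, cfg_dict, input_hashes)
        manifest.stages[stage] = {"key": key, "timestamp": time.time()}
        if old is None or stage not in old.stages:
            return False
        if old.stages[stage]["key"] != key:
            return False
        if not all(p.exists() for p in outputs):
            return False
        manifest.stages[stage]["cached"] = True
        return True

    rng_root = np.random.default_rng(config.seed)
    seeds = {name: int(rng_root.integers(2**31 - 1)) for name in
             ("genotypes", "phenotype", "leaves", "orchard", "cv")}

    # ---- stage: genotypes + breeding values --------------------------------
    geno_path = out / "genotypes.tsv"
    truth_path = out / "genetic_truth.csv"
    arch = syn.GeneticArchitecture(
        n_individuals=config.n_accessions,
        n_snps=config.n_snps,
        maf_low=config.maf_low,
        maf_high=config.maf_high,
        n_causal=config.n_causal,
        h2_true=config.h2_true,
        ld_block_size=config.ld_block_size,
        seed=seeds["genotypes"],
    )
    if not fresh("genotypes", [geno_path, truth_path], []):
        from leafscape.io import write_genotypes_tsv

        G = syn.simulate_genotypes(arch)
        G.sample_ids = [f"A{i:04d}" for i in range(config.n_accessions)]
        y_gen, bv = syn.simulate_phenotype(
            G, arch, rng=np.random.default_rng([seeds["phenotype"]])
        )
        write_genotypes_tsv(G, geno_path)
        z = (y_gen - y_gen.mean()) / (y_gen.std() or 1.0)
        log_ar = config.mean_log_aspect + config.sd_log_aspect * z
        pd.DataFrame(
            {
                "accession": G.sample_ids,
                "genetic_value": y_gen,
                "breeding_value": bv,
                "log_aspect_ratio": log_ar,
            }
        ).set_index("accession").to_csv(truth_path)
    from leafscape.io import read_genotypes_tsv

    G = read_genotypes_tsv(geno_path)
    truth = pd.read_csv(truth_path, index_col=0)

    # ---- stage: leaves + measurement + descriptors -------------------------
    traits_path = out / "accession_traits.csv"
    efd_scores_path = out / "efd_pc_scores.csv"
    ph_scores_path = out / "ph_pc_scores.csv"
    stage_outputs = [traits_path, efd_scores_path, ph_scores_path]
    if not fresh("measure", stage_outputs, [_hash_file(truth_path)]):
        rng = np.random.default_rng([seeds["leaves"]])
        rows = {}
        efd_feats, ph_feats = [], []
        img_dir = out / "images"
        if config.write_images:
            img_dir.mkdir(exist_ok=True)
        ph_cfg = ph_mod.PHConfig(
            n_rings=config.ph_rings,
            n_levels=config.ph_levels,
            bandwidth=config.ph_bandwidth,
            r_max=config.ph_r_max,
        )
        lo, hi = config.leaves_per_tree
        for acc, t in truth.iterrows():
            n_leaves = int(rng.integers(lo, hi + 1))
            leaf_traits, efds, phs = [], [], []
            for _ in range(n_leaves):
                ar = math.exp(t["log_aspect_ratio"] + rng.normal(0.0, 0.03))
                params = syn.LeafParams(
                    aspect_ratio=ar,
                    blade_scale=config.blade_scale_px * math.exp(rng.normal(0, 0.05)),
                    serration_amplitude=0.05,
                    serration_count=24,
                    petiole_length=0.15,
                    seed=int(rng.integers(2**31 - 1)),
                )
                outline = syn.generate_leaf_outline(params)
                img = syn.rasterize_outline(outline, scale=config.scale_cm_per_px)
                if config.write_images:
                    img.write(img_dir / f"{acc}_{len(leaf_traits)}.png")
                leaf_traits.append(linear_traits(img))
                contour = extract_contour(img).astype(float)
                contour[:, 1] *= -1  # y up for shape analysis
                coef = efd_mod.normalize_efd(
                    efd_mod.efd_coefficients(contour, config.efd_harmonics)
                )
                efds.append(efd_mod.drop_asymmetric(coef))
                phs.append(ph_mod.ph_descriptor(contour, ph_cfg))
            summ = summarize_tree(leaf_traits)
            row = dict(summ.means)
            row.update(summ.cvs)
            rows[acc] = row
            efd_feats.append(efds)
            ph_feats.append(phs)
        traits = pd.DataFrame.from_dict(rows, orient="index")
        traits.index.name = "accession"
        traits.to_csv(traits_path)

        efd_pca = ms.pca(efd_mod.efd_feature_matrix(efd_feats))
        ph_pca = ms.pca(ph_mod.ph_feature_matrix(ph_feats))
        for res, path, label in (
            (efd_pca, efd_scores_path, "EFD"),
            (ph_pca, ph_scores_path, "PH"),
        ):
            k = min(config.n_pcs_keep, res.n_components)
            df = pd.DataFrame(
                res.scores[:, :k],
                index=traits.index,
                columns=[f"{label}_PC{i + 1}" for i in range(k)],
            )
            df.to_csv(path)
            pd.Series(
                res.percent_variance[:k],
                index=df.columns,
                name="percent_variance",
            ).to_csv(str(path) + ".variance")
    traits = pd.read_csv(traits_path, index_col=0)
    efd_scores = pd.read_csv(efd_scores_path, index_col=0)
    ph_scores = pd.read_csv(ph_scores_path, index_col=0)

    # ---- stage: orchard + REML adjustment ----------------------------------
    adjusted_path = out / "adjusted_traits.csv"
    pheno = pd.concat([traits, efd_scores, ph_scores], axis=1)
    if not fresh("adjust", [adjusted_path], [_hash_file(traits_path)]):
        controls = list(pheno.index[:3])
        design = syn.OrchardDesignSim(
            n_rgrid=config.n_rgrid,
            n_cgrid=config.n_cgrid,
            var_r=config.var_r,
            var_c=config.var_c,
            var_rc=config.var_rc,
            var_resid=config.var_resid,
            control_accessions=tuple(controls),
            seed=seeds["orchard"],
        )
        # position effects act on the standardized scale so one variance
        # setting is meaningful across traits of very different units
        mu, sd = pheno.mean(), pheno.std(ddof=1).replace(0.0, 1.0)
        observed = syn.simulate_orchard((pheno - mu) / sd, design)
        adjusted_z = reml.adjust_traits(observed[pheno.columns], observed)
        adjusted = adjusted_z * sd + mu
        adjusted.index.name = "accession"
        adjusted.to_csv(adjusted_path)
    adjusted = pd.read_csv(adjusted_path, index_col=0)

    # ---- stage: phenomic statistics ----------------------------------------
    corr_path = out / "trait_correlations.csv"
    sma_path = out / "allometry_sma.csv"
    if not fresh("stats", [corr_path, sma_path], [_hash_file(adjusted_path)]):
        r, p = ms.corr_matrix(adjusted)
        r.to_csv(corr_path)
        p.to_csv(str(corr_path) + ".pvalues")
        fit = ms.sma_fit(
            np.log(adjusted["major_cm"]), np.log(adjusted["minor_cm"])
        )
        pd.DataFrame(
            [dataclasses.asdict(fit)]
        ).to_csv(sma_path, index=False)

    # ---- stage: genomics ----------------------------------------------------
    h2_path = out / "heritability.csv"
    pred_path = out / "prediction_accuracy.csv"
    gwas_path = out / "gwas_aspect_ratio.tsv"
    if not fresh("genomics", [h2_path, pred_path, gwas_path], [_hash_file(adjusted_path)]):
        K = gen.kinship(G)
        adj = adjusted.loc[[a for a in G.sample_ids if a in adjusted.index]]
        Ksub = K  # same ordering by construction
        h2_rows, pred_rows = [], []
        focus = ["aspect_ratio", "EFD_PC1", "PH_PC1", "major_cm", "minor_cm"]
        for trait in [t for t in focus if t in adj.columns]:
            yv = adj[trait].to_numpy()
            est = gen.greml_h2(yv, Ksub)
            h2_rows.append(
                {"trait": trait, "h2": est.h2, "se": est.se, "vg": est.vg, "ve": est.ve}
            )
            pr = gen.rrblup_cv(
                G, yv, folds=config.cv_folds, reps=config.cv_reps,
                seed=seeds["cv"], K=Ksub,
            )
            pred_rows.append({"trait": trait, "mean_r": pr.mean_r})
        pd.DataFrame(h2_rows).to_csv(h2_path, index=False)
        pd.DataFrame(pred_rows).to_csv(pred_path, index=False)
        gw = gen.mlm_gwas(
            G, adj["aspect_ratio"].to_numpy(), K=Ksub, n_pcs=config.gwas_pcs,
            compute_threshold=True,
        )
        gw.to_csv(gwas_path, sep="\t", index=False)
        (out / "gwas_threshold.json").write_text(
            json.dumps({"meff": gw.attrs["meff"], "threshold": gw.attrs["threshold"]})
        )

    manifest.save(manifest_path)
    return manifest


def report(manifest_path, out_path=None) -> Path:
    """Render a summary document with the run's key tables and figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manifest = RunManifest.load(manifest_path)
    run_dir = Path(manifest_path).parent
    out_path = Path(out_path) if out_path else run_dir / "report.md"
    required = ["adjusted_traits.csv", "trait_correlations.csv", "heritability.csv"]
    for name in required:
        if not (run_dir / name).exists():
            raise LeafscapeError(f"incomplete run: missing {name}")

    adjusted = pd.read_csv(run_dir / "adjusted_traits.csv", index_col=0)
    corr = pd.read_csv(run_dir / "trait_correlations.csv", index_col=0)
    h2 = pd.read_csv(run_dir / "heritability.csv")
    figs = []

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=6)
    fig.colorbar(im, label="Pearson r")
    p = run_dir / "fig_correlations.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    figs.append(p)

    if {"EFD_PC1", "aspect_ratio"} <= set(adjusted.columns):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(adjusted["aspect_ratio"], adjusted["EFD_PC1"], s=8)
        ax.set_xlabel("aspect ratio")
        ax.set_ylabel("EFD PC1")
        p = run_dir / "fig_pc1_vs_aspect.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        figs.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(h2["trait"], h2["h2"], yerr=h2["se"], capsize=3)
    ax.axhline(0, color="k", lw=0.8, ls=":")
    ax.set_ylabel("SNP heritability $h^2$")
    ax.tick_params(axis="x", rotation=45)
    p = run_dir / "fig_heritability.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    figs.append(p)

    gwas_file = run_dir / "gwas_aspect_ratio.tsv"
    if gwas_file.exists():
        gw = pd.read_csv(gwas_file, sep="\t")
        thr = json.loads((run_dir / "gwas_threshold.json").read_text())
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.scatter(range(len(gw)), -np.log10(gw["p"]), s=4)
        ax.axhline(-np.log10(thr["threshold"]), color="r", ls="--", lw=0.8)
        ax.set_xlabel("SNP index")
        ax.set_ylabel("-log10 p")
        p = run_dir / "fig_manhattan.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        figs.append(p)

    lines = [
        "# leafscape run report",
        "",
        f"seed: {manifest.config['seed']}",
        f"version: {manifest.version}",
        "",
        f"accessions (adjusted traits): {len(adjusted)}",
        "",
        "## traits",
        "",
        ", ".join(adjusted.columns),
        "",
        "## SNP heritability",
        "",
        h2.to_string(index=False),
        "",
        "## figures",
        "",
    ]
    lines += [f"![]({p.name})" for p in figs]
    out_path.write_text("\n".join(lines))
    for p in figs:
        if not p.exists():
            raise LeafscapeError(f"figure missing: {p}")
    return out_path
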