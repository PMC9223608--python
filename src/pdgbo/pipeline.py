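"""End-to-end orchestration: simulate -> quantify -> score -> calcium -> pathways.

Each stage writes its outputs into a run directory and records them in a
manifest with content hashes; a completed stage whose outputs are intact is
skipped on resume, and a deleted intermediate is regenerated bit-identically
because every stage draws from its own seed derived deterministically from
the run seed.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import calcium as ca
from . import imaging as im
from . import pathways as pw
from . import screen as sc
from . import simulate as sim
from .config import PipelineConfig

__all__ = ["RunReport", "run_all", "stage_seed", "STAGES"]

STAGES = ("simulate_screen", "images", "score", "calcium", "pathways")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (independent of execution order)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    seed: int
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    screen_report: dict | None = None
    imaging_summary: list[dict] | None = None
    calcium_summary: dict | None = None
    pathway_summary: dict | None = None

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


class _Runner:
    def __init__(self, config: PipelineConfig, outdir: str, resume: bool = True):
        self.cfg = config.validate()
        self.outdir = outdir
        self.resume = resume
        os.makedirs(outdir, exist_ok=True)
        self.manifest_path = os.path.join(outdir, "manifest.json")
        self.manifest: dict = {"stages": {}}
        if resume and os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        self.report = RunReport(seed=self.cfg.seed, config=self.cfg.to_dict())

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry:
            return False
        for f, digest in entry["outputs"].items():
            p = self.path(f)
            if not os.path.exists(p) or _sha256(p) != digest:
                return False
        return True

    def _finish(self, stage: str, outputs: list[str], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {f: _sha256(self.path(f)) for f in outputs},
            "seed": stage_seed(self.cfg.seed, stage),
            "elapsed_s": round(time.time() - t0, 3),
        }
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        self.report.stages[stage] = self.manifest["stages"][stage]

    # ----------------------------------------------------------- stages

    def simulate_screen(self) -> None:
        stage = "simulate_screen"
        if self.resume and self._done(stage):
            self.report.stages[stage] = self.manifest["stages"][stage]
            return
        t0 = time.time()
        s = self.cfg.screen
        seed = stage_seed(self.cfg.seed, stage)
        series = sim.make_dilution_series(s.top_conc_M, s.fold, s.n_points)
        layout = sim.make_plate_layout(
            s.n_drugs, series, s.n_replicates, n_vehicle=s.n_vehicle
        )
        hits = {}
        if s.hit_drug:
            hits[s.hit_drug] = sim.DrugTruth(
                top=1.0, bottom=s.hit_bottom, ic50=s.hit_ic50, hill=s.hit_hill
            )
        truth = sim.make_screen_truth(
            n_drugs=s.n_drugs, hit_drugs=hits, sigma=s.sigma, seed=seed
        )
        readouts = sim.simulate_viability(layout, truth, seed=seed)
        layout.to_csv(self.path("layout.csv"), index=False)
        readouts.to_csv(self.path("readouts.csv"), index=False)
        self._finish(stage, ["layout.csv", "readouts.csv"], t0)

    def images(self) -> None:
        stage = "images"
        if self.resume and self._done(stage):
            self.report.stages[stage] = self.manifest["stages"][stage]
            return
        t0 = time.time()
        c = self.cfg.imaging
        seed = stage_seed(self.cfg.seed, stage)
        img_dir = self.path("images")
        os.makedirs(img_dir, exist_ok=True)
        rows = []
        outputs = []
        for k in range(c.n_samples):
            sample = f"field_{k + 1}"
            truth = sim.make_image_truth(
                n_cells=c.n_cells,
                shape=(c.image_height, c.image_width, c.n_z),
                seed=seed + k,
            )
            imgs = sim.render_organoid_images(truth, seed=seed + 1000 + k)
            paths = imgs.save(img_dir, sample)
            outputs.extend(os.path.relpath(p, self.outdir) for p in paths)
            res = im.analyze_image_set(
                imgs,
                vital_k=c.vital_k,
                footprint_k=c.footprint_k,
                nuclei_sigma=c.nuclei_sigma,
                network_scales=tuple(c.network_scales),
                network_k=c.network_k,
            )
            row = res.to_row(sample=sample)
            row["true_network_ratio"] = (
                int(truth.nestin_mask().sum()) / int(truth.nuclei_mask().sum())
            )
            rows.append(row)
        summary = pd.DataFrame(rows)
        summary.to_csv(self.path("imaging_summary.csv"), index=False)
        self.report.imaging_summary = summary.to_dict(orient="records")
        self._finish(stage, ["imaging_summary.csv", *outputs], t0)

    def score(self) -> None:
        stage = "score"
        if self.resume and self._done(stage):
            self.report.stages[stage] = self.manifest["stages"][stage]
            self._load_screen_report()
            return
        t0 = time.time()
        layout = pd.read_csv(self.path("layout.csv"))
        readouts = pd.read_csv(self.path("readouts.csv"))
        rep = sc.score_screen(
            layout,
            readouts,
            sample_id="synthetic",
            positive_control=self.cfg.scoring.positive_control,
            z_strong=self.cfg.scoring.z_strong,
            z_weak=self.cfg.scoring.z_weak,
        )
        rep.to_frame().to_csv(self.path("scores.csv"), index=False)
        norm = sc.normalize_viability(readouts, layout)
        norm.to_csv(self.path("normalized_viability.csv"), index=False)
        with open(self.path("screen_report.json"), "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2)
        self.report.screen_report = rep.to_dict()
        self._finish(
            stage, ["scores.csv", "normalized_viability.csv", "screen_report.json"], t0
        )

    def _load_screen_report(self) -> None:
        p = self.path("screen_report.json")
        if os.path.exists(p):
            with open(p) as fh:
                self.report.screen_report = json.load(fh)

    def calcium(self) -> None:
        stage = "calcium"
        if self.resume and self._done(stage):
            self.report.stages[stage] = self.manifest["stages"][stage]
            return
        t0 = time.time()
        c = self.cfg.calcium
        seed = stage_seed(self.cfg.seed, stage)
        truth = sim.make_calcium_truth(
            n_cells=c.n_cells,
            duration=c.duration_s,
            frame_interval=c.frame_interval_s,
            rate_per_min=c.rate_per_min,
            amplitude=c.amplitude,
            noise_sd=c.noise_sd,
            seed=seed,
        )
        traces = sim.simulate_calcium_traces(truth, seed=seed + 1)
        traces.to_csv(self.path("traces.csv"), index=False)
        analysis = ca.analyze_traces(
            traces,
            frame_interval=c.frame_interval_s,
            smoothing_sigma=c.smoothing_sigma,
            min_prominence=c.min_prominence,
            tolerance_frames=c.tolerance_frames,
        )
        analysis.summary().to_csv(self.path("calcium_summary.csv"), index=False)
        analysis.synchrony_matrix.to_csv(self.path("synchrony.csv"))
        part = analysis.summary()["participation"].value_counts().to_dict()
        self.report.calcium_summary = {
            "participation_counts": part,
            "mean_frequency_per_min": float(
                np.mean(list(analysis.frequency.values()))
            ),
        }
        self._finish(
            stage, ["traces.csv", "calcium_summary.csv", "synchrony.csv"], t0
        )

    def pathways(self) -> None:
        stage = "pathways"
        if self.resume and self._done(stage):
            self.report.stages[stage] = self.manifest["stages"][stage]
            return
        t0 = time.time()
        p = self.cfg.pathways
        seed = stage_seed(self.cfg.seed, stage)
        rng = np.random.default_rng(seed)
        gene_sets: dict[str, list[str]] = {}
        gene_counter = 0
        for block in ("NEG", "POS", "MIX"):
            for i in range(p.n_pathways_per_block):
                genes = [
                    f"G{gene_counter + j:04d}" for j in range(p.genes_per_pathway)
                ]
                gene_counter += p.genes_per_pathway
                gene_sets[f"{block}_{i + 1}"] = genes
        # background genes belonging to no pathway
        background = [f"BG{j:04d}" for j in range(p.n_background_genes)]
        truth = sim.make_expression_truth(
            gene_sets,
            n_samples=p.n_samples,
            neg_pathways=[f"NEG_{i + 1}" for i in range(p.n_pathways_per_block)],
            pos_pathways=[f"POS_{i + 1}" for i in range(p.n_pathways_per_block)],
            mixed_pathways=[f"MIX_{i + 1}" for i in range(p.n_pathways_per_block)],
            seed=seed,
        )
        truth.genes = sorted(set(truth.genes) | set(background))
        expr, resp = sim.simulate_expression(truth, gene_sets, seed=seed + 1)
        del rng
        expr.to_csv(self.path("expression.tsv"), sep="\t")
        resp.to_csv(self.path("drug_response.tsv"), sep="\t")
        pw.write_gmt(gene_sets, self.path("gene_sets.gmt"))
        collection = pw.read_gmt(self.path("gene_sets.gmt"))
        es = pw.ssgsea_matrix(expr, collection, alpha=p.alpha)
        z, _ = pw.zscore_enrichment(es)
        rmat, n, flags = pw.correlate_drug_pathway(es, resp)
        order, labels = pw.cluster_pathways(rmat, k=p.cluster_k)
        drug_map = {
            d: list(links) for d, links in truth.drug_links.items() if links
        }
        reg = pw.regress_drug_on_target_pathways(es, resp, drug_map)
        es.to_csv(self.path("enrichment_es.tsv"), sep="\t")
        z.to_csv(self.path("enrichment_z.tsv"), sep="\t")
        rmat.to_csv(self.path("pathway_drug_r.tsv"), sep="\t")
        labels.to_frame().to_csv(self.path("pathway_clusters.csv"))
        reg.to_csv(self.path("target_pathway_regression.csv"), index=False)
        self.report.pathway_summary = {
            "n_pathways": int(len(es)),
            "n_samples": n,
            "flags": flags,
            "cluster_sizes": labels.value_counts().to_dict(),
            "dendrogram_order": order,
        }
        self._finish(
            stage,
            [
                "expression.tsv",
                "drug_response.tsv",
                "gene_sets.gmt",
                "enrichment_es.tsv",
                "enrichment_z.tsv",
                "pathway_drug_r.tsv",
                "pathway_clusters.csv",
                "target_pathway_regression.csv",
            ],
            t0,
        )


def run_all(
    config: PipelineConfig,
    outdir: str,
    resume: bool = True,
    stages: tuple[str, ...] = STAGES,
) -> RunReport:
    """Execute the stages in dependency order and write a RunReport JSON."""
    runner = _Runner(config, outdir, resume=resume)
    for stage in STAGES:
        if stage in stages:
            getattr(runner, stage)()
    runner.report.save(runner.path("run_report.json"))
    return runner.report
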