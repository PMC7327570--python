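"""End-to-end orchestration: simulate/load -> normalize -> Boruta -> MCFS -> IFS -> enrich.

One configuration drives the whole funnel.  Every stage receives its own
seed derived deterministically from the root seed and the stage name, every
intermediate artifact is written as plain TSV/JSON under the output
directory, and a manifest records, per stage, the parameters, seed and
SHA-256 of each output file, so any stage can be re-run standalone and
checked against the recorded hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import matrix as mio
from .synthetic import SyntheticConfig, generate_dataset
from .preprocess import quantile_normalize
from .boruta import BorutaParams, boruta_run, confirmed_features
from .mcfs import MCFSParams, run_mcfs, top_ranking_cutoff
from .ifs import (
    ClassifierParams,
    default_ifs_grid,
    ifs_curve,
    loocv_evaluate,
    select_signature,
)
from .enrichment import read_gmt, enrich

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "stage_seed", "run_pipeline"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (root seed, stage name), below 2^31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs.  Exactly one input source must be given:
    a synthetic-data config, or paths to a matrix TSV and a label TSV."""

    output_dir: str
    synthetic: SyntheticConfig | None = None
    matrix_path: str | None = None
    labels_path: str | None = None
    boruta: BorutaParams = field(default_factory=BorutaParams)
    mcfs: MCFSParams = field(default_factory=MCFSParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    cutoff_n_perm: int = 10
    cutoff_quantile: float = 0.95
    fixed_cutoff: int | None = None
    ifs_max_k: int | None = None
    gmt_path: str | None = None
    fdr_threshold: float = 0.05
    root_seed: int = 0

    def __post_init__(self):
        have_synth = self.synthetic is not None
        have_paths = self.matrix_path is not None and self.labels_path is not None
        if have_synth == have_paths:
            raise ValueError(
                "exactly one input source is required: either a synthetic config "
                "or matrix_path + labels_path"
            )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("synthetic") is not None:
            synth = dict(raw["synthetic"])
            for key in ("class_sizes", "class_names"):
                if synth.get(key) is not None:
                    synth[key] = tuple(synth[key])
            raw["synthetic"] = SyntheticConfig(**synth)
        for key, klass in (
            ("boruta", BorutaParams),
            ("mcfs", MCFSParams),
            ("classifier", ClassifierParams),
        ):
            if raw.get(key) is not None:
                raw[key] = klass(**raw[key])
        return cls(**raw)


@dataclass
class PipelineReport:
    """The funnel summary: how many genes survive each stage, and how well
    the final signature classifies."""

    n_samples: int
    n_genes_initial: int
    n_boruta_confirmed: int
    n_top_ranking: int
    k_star: int
    loocv_accuracy: float
    signature: list[str]
    per_class_accuracy: dict[str, float]
    n_significant_sets: int | None
    output_dir: str

    def funnel(self) -> list[tuple[str, int]]:
        return [
            ("input genes", self.n_genes_initial),
            ("Boruta confirmed", self.n_boruta_confirmed),
            ("top ranking", self.n_top_ranking),
            ("signature", self.k_star),
        ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(stage: str, params: dict, seed: int | None, files: list[Path]) -> None:
        manifest.append(
            {
                "stage": stage,
                "params": params,
                "seed": seed,
                "outputs": {f.name: _sha256(f) for f in files},
            }
        )

    def timed(stage):
        t0 = time.perf_counter()
        return lambda msg="": logger.info(
            "stage %-10s %5.1fs %s", stage, time.perf_counter() - t0, msg
        )

    # --- input -----------------------------------------------------------
    done = timed("input")
    if cfg.synthetic is not None:
        synth = dataclasses.replace(cfg.synthetic, seed=stage_seed(cfg.root_seed, "simulate"))
        m, labels, truth = generate_dataset(synth)
        truth.per_gene_class_means.rename_axis("gene_id").to_csv(
            out / "ground_truth.tsv", sep="\t"
        )
        params = asdict(synth)
    else:
        m = mio.read_matrix(cfg.matrix_path)
        labels = mio.read_labels(cfg.labels_path)
        labels = mio.validate_labels(labels, m)
        params = {"matrix_path": cfg.matrix_path, "labels_path": cfg.labels_path}
    mio.write_matrix(m, out / "matrix.tsv")
    mio.write_labels(labels, out / "labels.tsv")
    files = [out / "matrix.tsv", out / "labels.tsv"]
    if cfg.synthetic is not None:
        files.append(out / "ground_truth.tsv")
    record("input", params, params.get("seed"), files)
    done(f"{m.shape[0]} genes x {m.shape[1]} samples")

    # --- normalization ---------------------------------------------------
    done = timed("normalize")
    norm = quantile_normalize(m)
    mio.write_matrix(norm, out / "normalized.tsv")
    record("normalize", {}, None, [out / "normalized.tsv"])
    done()

    # --- Boruta all-relevant filter --------------------------------------
    done = timed("boruta")
    bparams = dataclasses.replace(cfg.boruta, seed=stage_seed(cfg.root_seed, "boruta"))
    bresult = boruta_run(norm, labels, bparams)
    confirmed = confirmed_features(bresult)
    boruta_table = pd.DataFrame(
        {
            "gene_id": bresult.status.index,
            "status": bresult.status.to_numpy(),
            "mean_importance": bresult.mean_importance().reindex(bresult.status.index).to_numpy(),
        }
    )
    boruta_table.to_csv(out / "boruta.tsv", sep="\t", index=False)
    record("boruta", asdict(bparams), bparams.seed, [out / "boruta.tsv"])
    done(f"{len(confirmed)} confirmed")

    # --- MCFS ranking ----------------------------------------------------
    done = timed("mcfs")
    # with zero confirmed genes (a null dataset) the ranking stage falls
    # back to all genes so the funnel can still be reported end to end
    mcfs_genes = confirmed if confirmed else list(norm.index)
    mparams = dataclasses.replace(
        cfg.mcfs,
        # an explicit subset size larger than the surviving gene count is
        # clamped rather than rejected: the funnel shrinks data under it
        m=None if cfg.mcfs.m is None else min(cfg.mcfs.m, len(mcfs_genes)),
        seed=stage_seed(cfg.root_seed, "mcfs"),
    )
    ranked, _ = run_mcfs(norm.loc[mcfs_genes], labels, mparams)
    ranked.to_frame().to_csv(out / "ranking.tsv", sep="\t", index=False)
    record("mcfs", asdict(mparams), mparams.seed, [out / "ranking.tsv"])
    done(f"ranked {ranked.N}")

    # --- top-ranking cutoff ----------------------------------------------
    done = timed("cutoff")
    cut_params = dataclasses.replace(mparams, seed=stage_seed(cfg.root_seed, "cutoff"))
    n_top = top_ranking_cutoff(
        ranked,
        norm.loc[mcfs_genes],
        labels,
        cut_params,
        n_perm=cfg.cutoff_n_perm,
        quantile=cfg.cutoff_quantile,
        fixed_k=cfg.fixed_cutoff,
    )
    done(f"cutoff {n_top}")

    # --- IFS + signature --------------------------------------------------
    done = timed("ifs")
    # even when the cutoff finds nothing above the null, sweep a few top
    # genes so the report carries a (near-chance) accuracy
    sweep_k = n_top if n_top >= 1 else min(20, ranked.N)
    if cfg.ifs_max_k is not None:
        sweep_k = min(sweep_k, cfg.ifs_max_k)
    cparams = dataclasses.replace(cfg.classifier, seed=stage_seed(cfg.root_seed, "ifs"))
    curve = ifs_curve(ranked, norm, labels, cparams, ks=default_ifs_grid(sweep_k))
    curve.to_frame().to_csv(out / "ifs_curve.tsv", sep="\t", index=False)
    k_star, signature = select_signature(curve, ranked)
    (out / "signature.txt").write_text("".join(g + "\n" for g in signature))
    accuracy, cm = loocv_evaluate(norm.loc[signature], labels, cparams)
    cm.to_table().rename_axis("").to_csv(out / "confusion.tsv", sep="\t")
    record(
        "ifs",
        {**asdict(cparams), "sweep_k": sweep_k},
        cparams.seed,
        [out / "ifs_curve.tsv", out / "signature.txt", out / "confusion.tsv"],
    )
    done(f"k*={k_star} acc={accuracy:.3f}")

    # --- enrichment (optional) -------------------------------------------
    n_significant = None
    if cfg.gmt_path is not None:
        done = timed("enrich")
        gsc = read_gmt(cfg.gmt_path)
        table = enrich(
            signature, gsc, universe=list(norm.index), fdr_threshold=cfg.fdr_threshold
        )
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        n_significant = int(table["significant"].sum()) if not table.empty else 0
        record(
            "enrich",
            {"gmt_path": cfg.gmt_path, "fdr_threshold": cfg.fdr_threshold},
            None,
            [out / "enrichment.tsv"],
        )
        done(f"{n_significant} significant sets")

    report = PipelineReport(
        n_samples=m.shape[1],
        n_genes_initial=m.shape[0],
        n_boruta_confirmed=len(confirmed),
        n_top_ranking=n_top,
        k_star=k_star,
        loocv_accuracy=accuracy,
        signature=signature,
        per_class_accuracy={c: float(a) for c, a in cm.per_class_accuracy.items()},
        n_significant_sets=n_significant,
        output_dir=str(out),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "report.json").write_text(json.dumps(asdict(report), indent=2) + "\n")
    return report
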