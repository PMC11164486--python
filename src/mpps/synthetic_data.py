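"""Synthetic multi-cohort expression/survival data with known ground truth.

Emulates the structure the pair-signature analysis assumes: a shared
pathway catalog; per-sample latent pathway activities; pathway-coherent
log-scale expression; event times from a proportional-hazards model on
TRUE binary pair indicators (activity_a > activity_b); independent
early-dropout censoring calibrated to a target fraction; and per-cohort
"platform" distortions (strictly increasing per-sample maps, gene dropout,
batch offsets) mimicking different sequencing platforms.

All randomness flows from a single root seed through named substreams, so
cohorts are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_set_scoring import GeneSetCollection
from .model_training import SurvivalData
from .pair_features import pair_id

logger = logging.getLogger("mpps")

__all__ = ["SimulationConfig", "GroundTruth", "Cohort", "simulate_cohort", "apply_platform_shift", "make_benchmark_suite"]

# substream labels -> fixed integers mixed into the seed sequence
_STREAMS = {"catalog": 11, "activities": 13, "noise": 17, "survival": 19, "censoring": 23, "platform": 29}


def _rng(root_seed: int, cohort_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([root_seed, cohort_seed, _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults describe a training-cohort-sized study: 600 samples, a
    20-pathway catalog over 2000 genes (60 genes each, 10% drawn from a
    shared pool), three causal pathway pairs with log hazard ratios
    +1.0/+0.8/-0.9, an exponential baseline hazard of 0.1 per time unit
    (years), and 30% independent censoring. Noise scales are calibrated so
    pathway scores track the latent activities (corr > 0.6) and the
    pipeline's pair bits agree with the true indicators for >= 90% of
    samples.
    """

    n_genes: int = 2000
    n_pathways: int = 20
    genes_per_pathway: int = 60
    overlap_fraction: float = 0.1
    n_samples: int = 600
    causal_pairs: list = field(
        default_factory=lambda: [("PW03", "PW04", 1.0), ("PW07", "PW08", 0.8), ("PW11", "PW12", -0.9)]
    )
    baseline: dict = field(default_factory=lambda: {"distribution": "exponential", "scale": 0.1, "shape": 1.0})
    censoring: dict = field(default_factory=lambda: {"target_fraction": 0.30, "admin_time": None})
    platform: dict = field(
        default_factory=lambda: {"monotone_family": "affine_power", "dropout_fraction": 0.05, "batch_shift_sd": 0.2}
    )
    # latent-activity scales: pathway means spread between_sd apart, causal
    # pairs separated by causal_separation, per-sample jitter activity_sd
    between_sd: float = 1.0
    causal_separation: float = 0.4
    activity_sd: float = 1.0
    noise_sd: float = 0.7
    baseline_mean: float = 5.0
    baseline_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        names = set(self.pathway_names())
        for a, b, hr in self.causal_pairs:
            if a not in names or b not in names:
                raise ValueError(f"causal pair ({a}, {b}) names a pathway outside the catalog")
            if not np.isfinite(hr):
                raise ValueError(f"log hazard ratio for ({a}, {b}) must be finite")
        if not (0 <= self.censoring["target_fraction"] < 1):
            raise ValueError("censoring target fraction must be in [0, 1)")
        if self.baseline["distribution"] not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline distribution {self.baseline['distribution']!r}")

    def pathway_names(self) -> list[str]:
        width = max(2, len(str(self.n_pathways)))
        return [f"PW{i + 1:0{width}d}" for i in range(self.n_pathways)]


@dataclass
class GroundTruth:
    """What the generator knows: latent activities, true pair bits, predictor, raw times."""

    activities: pd.DataFrame  # pathways x samples
    true_pair_values: pd.DataFrame  # causal pairs x samples, 0/1
    linear_predictor: pd.Series
    event_times: pd.Series  # uncensored


@dataclass
class Cohort:
    name: str
    expression: pd.DataFrame
    gene_sets: GeneSetCollection
    survival: SurvivalData
    truth: GroundTruth


def _build_catalog(cfg: SimulationConfig) -> tuple[GeneSetCollection, dict]:
    """Pathway catalog with a shared-gene pool giving the configured overlap."""
    rng = _rng(cfg.seed, 0, "catalog")
    n_shared = int(round(cfg.overlap_fraction * cfg.genes_per_pathway))
    n_unique = cfg.genes_per_pathway - n_shared
    pool_size = max(n_shared * 2, cfg.genes_per_pathway) if n_shared else 0
    needed = pool_size + cfg.n_pathways * n_unique
    if needed > cfg.n_genes:
        raise ValueError(f"catalog needs {needed} genes but n_genes={cfg.n_genes}")
    width = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    pool = genes[:pool_size]
    cursor = pool_size
    sets: dict[str, list[str]] = {}
    membership: dict[str, list[int]] = {}  # gene -> pathway indices
    for pi, name in enumerate(cfg.pathway_names()):
        own = genes[cursor : cursor + n_unique]
        cursor += n_unique
        shared = list(rng.choice(pool, size=n_shared, replace=False)) if n_shared else []
        members = own + shared
        sets[name] = members
        for g in members:
            membership.setdefault(g, []).append(pi)
    coll = GeneSetCollection(sets=sets, descriptions={n: "synthetic pathway" for n in sets})
    return coll, {"genes": genes, "membership": membership}


def simulate_cohort(cfg: SimulationConfig, cohort_seed: int) -> Cohort:
    """One cohort: expression, catalog, survival and ground truth.

    The catalog depends only on the root seed, so cohorts simulated from the
    same config share it. Event times follow a proportional-hazards model on
    the true pair indicators; censoring is an independent early-dropout
    process (uniform on a short initial window) calibrated to the target
    fraction, which keeps the censoring indicator nearly uncorrelated with
    the linear predictor.
    """
    catalog, info = _build_catalog(cfg)
    names = cfg.pathway_names()
    samples = [f"C{cohort_seed}S{i + 1:04d}" for i in range(cfg.n_samples)]

    rng_act = _rng(cfg.seed, cohort_seed, "activities")
    mu = rng_act.normal(0.0, cfg.between_sd, size=cfg.n_pathways)
    # causal pairs get a fixed mean separation so their prevalence stays
    # inside the [0.2, 0.8] filter window
    idx = {n: i for i, n in enumerate(names)}
    for a, b, _ in cfg.causal_pairs:
        centre = (mu[idx[a]] + mu[idx[b]]) / 2.0
        mu[idx[a]] = centre + cfg.causal_separation / 2.0
        mu[idx[b]] = centre - cfg.causal_separation / 2.0
    act = mu[:, None] + rng_act.normal(0.0, cfg.activity_sd, size=(cfg.n_pathways, cfg.n_samples))
    activities = pd.DataFrame(act, index=names, columns=samples)

    rng_noise = _rng(cfg.seed, cohort_seed, "noise")
    baseline = rng_noise.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    expr = np.tile(baseline[:, None], (1, cfg.n_samples))
    gene_index = {g: i for i, g in enumerate(info["genes"])}
    for g, pws in info["membership"].items():
        expr[gene_index[g]] += act[pws].mean(axis=0)
    expr += rng_noise.normal(0.0, cfg.noise_sd, size=expr.shape)
    expression = pd.DataFrame(expr, index=info["genes"], columns=samples)

    # true pair bits and the proportional-hazards linear predictor
    tp_rows = {}
    eta = np.zeros(cfg.n_samples)
    for a, b, log_hr in cfg.causal_pairs:
        z = (act[idx[a]] > act[idx[b]]).astype(int)
        tp_rows[pair_id(a, b)] = z
        eta += log_hr * z
    true_pairs = pd.DataFrame(tp_rows, index=samples).T

    rng_surv = _rng(cfg.seed, cohort_seed, "survival")
    scale = float(cfg.baseline["scale"])
    shape = float(cfg.baseline.get("shape", 1.0))
    e_std = rng_surv.exponential(1.0, size=cfg.n_samples)
    if cfg.baseline["distribution"] == "exponential":
        T = e_std / (scale * np.exp(eta))
    else:  # weibull: cumulative hazard scale * t^shape * exp(eta)
        T = (e_std / (scale * np.exp(eta))) ** (1.0 / shape)

    time, event = _censor(cfg, cohort_seed, T)
    survival = SurvivalData.from_arrays(samples, time, event)
    truth = GroundTruth(
        activities=activities,
        true_pair_values=true_pairs,
        linear_predictor=pd.Series(eta, index=samples, name="linear_predictor"),
        event_times=pd.Series(T, index=samples, name="event_time"),
    )
    return Cohort(name=f"cohort{cohort_seed}", expression=expression, gene_sets=catalog, survival=survival, truth=truth)


def _censor(cfg: SimulationConfig, cohort_seed: int, T: np.ndarray):
    """Independent early-dropout censoring calibrated to the target fraction.

    A calibrated fraction of subjects is at risk of dropout, with dropout
    times uniform on [0, w] where w is 5% of the baseline mean lifetime —
    short relative to survival differences, so whether a subject is censored
    carries almost no information about their risk.
    """
    target = float(cfg.censoring["target_fraction"])
    admin = cfg.censoring.get("admin_time")
    n = len(T)
    if admin is not None:
        admin = float(admin)
        frac_admin = float(np.mean(T > admin))
        if frac_admin > target:
            raise ValueError(
                f"infeasible censoring target {target}: administrative time {admin} "
                f"alone censors {frac_admin:.3f} of subjects"
            )
    if target == 0 and admin is None:
        return T.copy(), np.ones(n, dtype=int)

    scale = float(cfg.baseline["scale"])
    if cfg.baseline["distribution"] == "exponential":
        mean_life = 1.0 / scale
    else:
        from scipy.special import gamma as _gamma

        shape = float(cfg.baseline.get("shape", 1.0))
        mean_life = (1.0 / scale) ** (1.0 / shape) * _gamma(1.0 + 1.0 / shape)
    w = 0.05 * mean_life

    under_admin = T <= admin if admin is not None else np.ones(n, dtype=bool)
    # P(censored_i | at dropout risk) for uniform dropout on [0, w]
    p_drop = np.minimum(T, w) / w
    numer = target - (0.0 if admin is None else float(np.mean(~under_admin)))
    denom = float(np.mean(p_drop * under_admin))
    q = 0.0 if denom == 0 else numer / denom
    if q > 1.0 + 1e-9:
        raise ValueError(
            f"infeasible censoring target {target}: even universal dropout risk yields only "
            f"{denom + (0.0 if admin is None else float(np.mean(~under_admin))):.3f}"
        )
    q = min(max(q, 0.0), 1.0)

    rng = _rng(cfg.seed, cohort_seed, "censoring")
    at_risk = rng.random(n) < q
    C = np.where(at_risk, rng.uniform(0.0, w, size=n), np.inf)
    if admin is not None:
        C = np.minimum(C, admin)
    event = (T <= C).astype(int)
    time = np.minimum(T, C)
    time = np.maximum(time, 1e-9)  # survival times must stay positive
    return time, event


def apply_platform_shift(
    expr: pd.DataFrame,
    platform: dict,
    seed: int,
    gene_sets: GeneSetCollection | None = None,
    min_size: int = 5,
) -> pd.DataFrame:
    """Distort a cohort the way a different platform would.

    Per-gene batch offsets are added first, a random `dropout_fraction` of
    genes is removed, and finally an independent strictly increasing map is
    applied to every sample (family "affine_power": x -> a*(x - m + 1)^p + b
    on values shifted positive, or "identity"). Because the monotone map is
    last, within-sample rank order is set by the distorted values. Warns if
    dropout pushes any provided gene set below `min_size`.
    """
    family = platform.get("monotone_family", "identity")
    dropout = float(platform.get("dropout_fraction", 0.0))
    batch_sd = float(platform.get("batch_shift_sd", 0.0))
    if family not in ("identity", "affine_power"):
        raise ValueError(f"unknown monotone family {family!r}")
    if not (0 <= dropout < 1):
        raise ValueError("dropout_fraction must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAMS["platform"]]))

    values = expr.to_numpy(dtype=float).copy()
    if batch_sd > 0:
        values += rng.normal(0.0, batch_sd, size=(values.shape[0], 1))

    keep_idx = np.arange(values.shape[0])
    if dropout > 0:
        n_drop = int(round(dropout * len(keep_idx)))
        dropped = rng.choice(len(keep_idx), size=n_drop, replace=False)
        keep_mask = np.ones(len(keep_idx), dtype=bool)
        keep_mask[dropped] = False
        keep_idx = keep_idx[keep_mask]
        values = values[keep_mask]
    genes = expr.index[keep_idx]

    if family == "affine_power":
        m = values.min()
        shifted = values - m + 1.0  # strictly positive
        a = rng.uniform(0.5, 2.0, size=values.shape[1])
        p = rng.uniform(0.5, 2.0, size=values.shape[1])
        b = rng.normal(0.0, 1.0, size=values.shape[1])
        values = a[None, :] * shifted ** p[None, :] + b[None, :]

    out = pd.DataFrame(values, index=genes, columns=expr.columns)
    if gene_sets is not None and dropout > 0:
        affected = [
            name
            for name, members in gene_sets.sets.items()
            if out.index.isin(members).sum() < min_size
        ]
        if affected:
            logger.warning("platform dropout leaves pathways below min_size=%d: %s", min_size, affected)
    return out


def make_benchmark_suite(cfg: SimulationConfig, k_validation: int = 6, out_dir=None) -> dict:
    """One undistorted training cohort plus k platform-shifted validation cohorts.

    All cohorts share the catalog and causal structure; each validation
    cohort gets its own samples, monotone distortion, batch offsets and gene
    dropout. With `out_dir`, writes each cohort's expression TSV, clinical
    TSV, the shared GMT and a JSON manifest of files and seeds.
    """
    if k_validation < 1:
        raise ValueError("need at least one validation cohort")
    train = simulate_cohort(cfg, cohort_seed=1)
    validations = []
    for k in range(k_validation):
        cohort_seed = 101 + k
        cohort = simulate_cohort(cfg, cohort_seed=cohort_seed)
        shifted = apply_platform_shift(
            cohort.expression, cfg.platform, seed=cfg.seed * 1000 + cohort_seed, gene_sets=cohort.gene_sets
        )
        validations.append(
            Cohort(
                name=f"validation{k + 1}",
                expression=shifted,
                gene_sets=cohort.gene_sets,
                survival=cohort.survival,
                truth=cohort.truth,
            )
        )
    suite = {"train": train, "validation": validations}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": cfg.seed, "config": asdict(cfg), "cohorts": []}
        gmt_path = out / "pathways.gmt"
        with open(gmt_path, "w") as fh:
            for name, genes in train.gene_sets.sets.items():
                fh.write("\t".join([name, train.gene_sets.descriptions.get(name, "")] + genes) + "\n")
        for cohort, cseed in [(train, 1)] + [(v, 101 + i) for i, v in enumerate(validations)]:
            cdir = out / cohort.name
            cdir.mkdir(exist_ok=True)
            cohort.expression.to_csv(cdir / "expression.tsv", sep="\t", index_label="gene_id")
            clin = cohort.survival.frame.copy()
            clin.to_csv(cdir / "clinical.tsv", sep="\t", index_label="sample_id")
            manifest["cohorts"].append(
                {
                    "name": cohort.name,
                    "cohort_seed": cseed,
                    "expression": str(cdir / "expression.tsv"),
                    "clinical": str(cdir / "clinical.tsv"),
                    "gmt": str(gmt_path),
                }
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        suite["manifest"] = manifest
    return suite
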