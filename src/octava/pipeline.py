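"""End-to-end synthetic-cohort experiment and group statistics.

``run_experiment`` runs the full enhancement experiment on simulated
eyes: a training cohort provides (single-shot, averaged) pairs that train
the denoiser; a disjoint test cohort is then processed into the three
images per eye — original (frame 0), averaged (registered 10-frame mean),
and denoised (network output on the original) — and every image-quality
and vascular metric is computed on each.

``compare_groups`` applies the experiment's statistical scheme: per metric a
one-way ANOVA across the three image groups with Tukey HSD pairwise
adjusted p-values, except PSNR which exists only for original and
denoised images (both measured against the averaged reference) and is
compared by a paired t-test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_io import EnFaceImage, write_enface
from .denoiser import (
    DenoiserConfig,
    TrainedDenoiser,
    concat_pair_sets,
    denoise_image,
    extract_patches,
    train_denoiser,
)
from .enhance_average import average_frames, register_frames
from .qc_metrics import cnr, place_cnr_rois, psnr
from .synthdata import FrameStack, NoiseParams, simulate_eye
from .vessel_metrics import (
    MetricsRecord,
    binarize,
    fractal_dimension,
    skeletonize_mask,
    vessel_density,
    vessel_diameter_index,
    vessel_length_density,
)

__all__ = ["ExperimentConfig", "StatsReport", "run_experiment", "compare_groups", "eye_triplet"]

GROUPS = ("original", "averaged", "denoised")
ANOVA_METRICS = ("cnr", "vd", "vld_per_mm", "vdi_px", "fd")


@dataclass
class ExperimentConfig:
    """Scale and parameters of one synthetic-cohort experiment.

    Train and test eyes draw their seeds from disjoint streams spawned
    from ``seed``, so the held-out cohort never overlaps the training one.
    """

    n_train_eyes: int = 20
    n_test_eyes: int = 10
    n_frames: int = 10
    field_px: int = 232
    noise: NoiseParams = field(default_factory=NoiseParams)
    denoiser: DenoiserConfig = field(
        default_factory=lambda: DenoiserConfig(
            depth=3, base_channels=8, patch_px=32, stride_px=16, n_steps=800, batch_size=16
        )
    )
    max_shift: int = 6
    resample_500: bool = True
    seed: int = 0
    out_dir: str | None = None


@dataclass
class StatsReport:
    """Per-group summaries and pairwise comparisons for every metric."""

    groups: tuple[str, ...]
    metrics: dict  # metric -> {means, sds, anova_p, tukey: {"a|b": p}}
    psnr_paired: dict  # {mean_original, mean_denoised, sd_*, t, p}

    def tukey_p(self, metric: str, a: str, b: str) -> float:
        """Adjusted pairwise p-value for groups a, b (order-insensitive)."""
        t = self.metrics[metric]["tukey"]
        return t.get(f"{a}|{b}", t.get(f"{b}|{a}"))

    def to_json(self) -> str:
        return json.dumps({"groups": list(self.groups), "metrics": self.metrics,
                           "psnr_paired": self.psnr_paired}, indent=1)

    def to_markdown(self) -> str:
        lines = ["| metric | " + " | ".join(self.groups) + " | ANOVA p |", "|---" * 5 + "|"]
        for m, d in self.metrics.items():
            cells = [f"{d['means'][g]:.4g} ± {d['sds'][g]:.3g}" for g in self.groups]
            lines.append(f"| {m} | " + " | ".join(cells) + f" | {d['anova_p']:.3g} |")
        p = self.psnr_paired
        lines.append(
            f"| psnr_db | {p['mean_original']:.4g} ± {p['sd_original']:.3g} | — | "
            f"{p['mean_denoised']:.4g} ± {p['sd_denoised']:.3g} | {p['p']:.3g} (paired t) |"
        )
        return "\n".join(lines)


def eye_triplet(
    stack: FrameStack, model: TrainedDenoiser, max_shift: int = 6
) -> dict[str, EnFaceImage]:
    """Produce the three analysis images for one eye from its frame stack."""
    reg = register_frames(stack, max_shift=max_shift)
    averaged = average_frames(stack, reg)
    denoised = denoise_image(model, stack.original)
    return {"original": stack.original, "averaged": averaged, "denoised": denoised}


def _metrics_row(
    eye_id: str,
    label: str,
    image: EnFaceImage,
    rois,
    reference: EnFaceImage | None,
    resample_500: bool,
) -> dict:
    _, cnr_val = cnr(image, rois)
    psnr_db = psnr(image, reference).psnr_db if reference is not None else np.nan
    mask = binarize(image, resample_to_500=resample_500)
    skel = skeletonize_mask(mask)
    record = MetricsRecord(
        eye_id=eye_id,
        label=label,
        vd=vessel_density(mask),
        vld_per_mm=vessel_length_density(skel),
        vdi_px=vessel_diameter_index(mask, skel),
        fd=fractal_dimension(skel),
        cnr=cnr_val,
        psnr_db=psnr_db,
    )
    return asdict(record)


def run_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, StatsReport, TrainedDenoiser]:
    """Run the full synthetic experiment; returns (metrics table, report, model).

    Stages: simulate training eyes -> train the denoiser on
    (frame 0, averaged) patch pairs -> simulate held-out test eyes ->
    build the original/averaged/denoised triplet per eye -> compute CNR
    (one ROI set per eye reused across the three images), PSNR of original
    and denoised versus averaged, and VD/VLD/VDI/FD on all three ->
    aggregate and compare groups.  Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence([config.seed, 0xE7E])
    train_ss, test_ss = ss.spawn(2)
    train_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in train_ss.spawn(config.n_train_eyes)]
    test_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in test_ss.spawn(config.n_test_eyes)]

    pair_sets = []
    for i, s in enumerate(train_seeds):
        try:
            stack = simulate_eye(config.noise, config.n_frames, seed=s, field_px=config.field_px)
            reg = register_frames(stack, max_shift=config.max_shift)
            averaged = average_frames(stack, reg)
            pair_sets.append(
                extract_patches(stack.original, averaged, config.denoiser, eye_id=f"train{i:03d}")
            )
        except Exception as e:  # annotate stage + eye, then re-raise
            raise RuntimeError(f"training-eye train{i:03d} failed during simulation/averaging") from e
    model = train_denoiser(concat_pair_sets(pair_sets), config.denoiser)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, s in enumerate(test_seeds):
        eye_id = f"test{i:03d}"
        try:
            stack = simulate_eye(config.noise, config.n_frames, seed=s, field_px=config.field_px)
            triplet = eye_triplet(stack, model, max_shift=config.max_shift)
            # one ROI set per eye, centered on the true FAZ, shared by all three
            rois = place_cnr_rois(triplet["original"], faz_center=stack.truth.faz_center)
            for label in GROUPS:
                ref = triplet["averaged"] if label in ("original", "denoised") else None
                rows.append(
                    _metrics_row(eye_id, label, triplet[label], rois, ref, config.resample_500)
                )
            if out_dir:
                for label, img in triplet.items():
                    write_enface(img, out_dir / f"{eye_id}_{label}.png")
        except Exception as e:
            raise RuntimeError(f"test-eye {eye_id} failed") from e

    table = pd.DataFrame(rows)
    report = compare_groups(table)
    if out_dir:
        table.to_csv(out_dir / "metrics.csv", index=False)
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.md").write_text(report.to_markdown() + "\n")
    return table, report, model


def compare_groups(table: pd.DataFrame) -> StatsReport:
    """Group statistics across original/averaged/denoised images.

    Per metric: mean ± SD per group, one-way ANOVA p, and Tukey HSD
    adjusted pairwise p-values.  PSNR (defined versus the averaged
    reference, hence only for original and denoised) is compared by a
    paired t-test across eyes.
    """
    labels = set(table["label"])
    if labels != set(GROUPS):
        raise ValueError(f"expected groups {GROUPS}, got {sorted(labels)}")
    counts = table.groupby("label")["eye_id"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced groups")
    if counts.iloc[0] < 3:
        raise ValueError("need at least 3 eyes per group")

    metrics_out: dict[str, dict] = {}
    for metric in ANOVA_METRICS:
        samples = [table.loc[table["label"] == g, metric].to_numpy() for g in GROUPS]
        if np.ptp(np.concatenate(samples)) == 0:
            # all observations identical: no effect by convention
            anova_p = 1.0
            tukey = {f"{a}|{b}": 1.0 for ai, a in enumerate(GROUPS) for b in GROUPS[ai + 1 :]}
        else:
            anova_p = float(sps.f_oneway(*samples).pvalue)
            res = pairwise_tukeyhsd(
                endog=table[metric].to_numpy(),
                groups=table["label"].to_numpy(),
                alpha=0.05,
            )
            gu = list(res.groupsunique)
            pairs = [(gu[i], gu[j]) for i, j in zip(*np.triu_indices(len(gu), 1))]
            tukey = {f"{a}|{b}": float(p) for (a, b), p in zip(pairs, res.pvalues)}
        metrics_out[metric] = {
            "means": {g: float(s.mean()) for g, s in zip(GROUPS, samples)},
            "sds": {g: float(s.std(ddof=1)) for g, s in zip(GROUPS, samples)},
            "anova_p": anova_p,
            "tukey": tukey,
        }

    piv = table.pivot(index="eye_id", columns="label", values="psnr_db")
    orig, den = piv["original"].to_numpy(), piv["denoised"].to_numpy()
    if np.allclose(orig, den):
        t_stat, p_val = 0.0, 1.0
    else:
        t_res = sps.ttest_rel(den, orig)
        t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
    psnr_paired = {
        "mean_original": float(np.mean(orig)),
        "sd_original": float(np.std(orig, ddof=1)),
        "mean_denoised": float(np.mean(den)),
        "sd_denoised": float(np.std(den, ddof=1)),
        "t": t_stat,
        "p": p_val,
    }
    return StatsReport(groups=GROUPS, metrics=metrics_out, psnr_paired=psnr_paired)
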