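"""Self-contained synthetic studies exercising the whole method.

Each study fixes its own cohort conditions (sample sizes, effect sizes,
missingness, slide geometry) and reports the quantities a practitioner would
check: does learned fusion keep up with the best single modality, does the
weight optimizer find an informative source, does t-test screening recover
planted biomarkers, and is the patient-wise CV leak-free.  The studies are
deterministic given their seed.

Problem sizes are chosen to be desk-scale: 200 patients per class, 100
features per molecular modality (10% informative), and 3x3-tile slides of
32-px tiles — small enough to run in minutes while leaving every stage
(screening, ranking, grid search, tile voting, weight training) with real
work to do.
"""
from __future__ import annotations

import numpy as np

from .evaluation import PipelineConfig, run_fusion_experiment, stratified_patientwise_kfold
from .features import TTestSelectionConfig, ttest_screen
from .fusion import FusionTrainConfig, optimize_weights
from .models import SVMConfig
from .synthetic import CohortSpec, SlideSpec, generate_cohort, generate_slide
from .types import DEFAULT_CLASSES, ProbabilityTable
from .wsi import extract_tiles

#: Per-modality between-class shifts (in within-class SD units) spanning a
#: weak (CNV-like) to a strong (RNA-like) source.
MOLECULAR_EFFECTS = {"RNA-Seq": 2.0, "miRNA-Seq": 1.6, "CNV": 0.8, "metDNA": 1.2}

#: Fusion-weight training configuration for the synthetic studies.  With only
#: a few hundred training samples and 5 epochs (~75 Adam steps), the paper's
#: neural-network-scale step size would barely move the randomly initialized
#: raw weights, so the studies use a step size of 0.05.
STUDY_FUSION = dict(learning_rate=0.05, batch_size=32)


def build_study_cohort(seed: int = 0, n_per_class: int = 200):
    """Synthetic 3-class cohort: 4 molecular modalities plus tiled slides.

    Every modality (slides included) is missing completely at random for 10%
    of patients.  Returns ``(cohort, tile_sets)``.
    """
    spec = CohortSpec(
        n_patients_per_class=n_per_class,
        classes=DEFAULT_CLASSES,
        modalities=tuple(MOLECULAR_EFFECTS),
        n_features=100,
        effect_size=MOLECULAR_EFFECTS,
        missing_rate=0.1,
        informative_fraction=0.1,
        seed=seed,
    )
    cohort = generate_cohort(spec)

    slide_spec = SlideSpec(grid=3, tile_px=32, background_fraction=0.25, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    tile_sets = {}
    for pid, label in cohort.patients["label"].items():
        if rng.random() < 0.1:  # slide missing for this patient
            continue
        img = generate_slide(slide_spec, label, rng=rng)
        tile_sets[pid] = extract_tiles(
            img, slide_spec.tile_px, slide_id=pid, patient_id=pid, label=label
        )
    return cohort, tile_sets


def fusion_benefit_study(seed: int = 0, n_per_class: int = 200, k_folds: int = 10) -> dict:
    """Cross-validated fused-vs-single-modality comparison.

    Runs the full pipeline (per-fold screening, mRMR, SVM grid search, tile
    voting, weight optimization) and compares the fused weighted F1 against
    the best single modality, each modality scored on its own available test
    samples and the fused model on all samples with at least one source.
    """
    cohort, tile_sets = build_study_cohort(seed=seed, n_per_class=n_per_class)
    config = PipelineConfig(
        n_select=10,
        screen=TTestSelectionConfig(required_comparisons=2, mean_diff_threshold=0.4),
        svm=SVMConfig(seed=seed),
        fusion=FusionTrainConfig(epochs=5, seed=seed, **STUDY_FUSION),
        k_folds=k_folds,
        seed=seed,
    )
    result = run_fusion_experiment(cohort, config, tile_sets=tile_sets, regime="all")
    single_f1 = {
        mod: float(np.mean([r.f1_weighted for r in reports]))
        for mod, reports in result.per_modality.items()
        if reports
    }
    fused_f1 = float(np.mean([r.f1_weighted for r in result.fused]))
    best_mod = max(single_f1, key=single_f1.get)
    return {
        "fused_f1": fused_f1,
        "single_f1": single_f1,
        "best_single_modality": best_mod,
        "best_single_f1": single_f1[best_mod],
        "margin_pp": 100.0 * (fused_f1 - single_f1[best_mod]),
        "n_patients": len(cohort.patients),
        "result": result,
    }


def make_oracle_uniform_table(
    n: int, rng: np.random.Generator, classes=DEFAULT_CLASSES
) -> tuple[ProbabilityTable, np.ndarray]:
    """Two-modality table: an oracle source (probability 1 on the true class)
    and a uniform-random source; used to check weight recovery."""
    y = rng.integers(0, len(classes), n)
    P = np.zeros((n, 2, len(classes)))
    P[np.arange(n), 0, y] = 1.0
    u = rng.random((n, len(classes)))
    P[:, 1, :] = u / u.sum(axis=1, keepdims=True)
    table = ProbabilityTable(
        sample_ids=[f"s{i}" for i in range(n)],
        classes=tuple(classes),
        modalities=("oracle", "noise"),
        probs=P,
        mask=np.ones((n, 2), dtype=bool),
    )
    return table, np.asarray(classes)[y]


def weight_recovery_study(n_repeats: int = 100, n: int = 500, seed: int = 0) -> dict:
    """Fraction of seeded repeats in which the oracle modality earns the
    largest projected weight in every class row."""
    rng = np.random.default_rng(seed)
    successes = 0
    for rep in range(n_repeats):
        table, labels = make_oracle_uniform_table(n, rng)
        cfg = FusionTrainConfig(
            epochs=30, seed=int(rng.integers(0, 2**31 - 1)), **STUDY_FUSION
        )
        weights = optimize_weights(table, labels, cfg)
        if (weights.projected.argmax(axis=1) == 0).all():
            successes += 1
    return {"successes": successes, "n_repeats": n_repeats, "rate": successes / n_repeats}


def selection_recovery_study(
    seed: int = 0, n_per_class: int = 200, n_features: int = 200, effect_size: float = 1.0
) -> dict:
    """Planted-biomarker recovery of the t-test screen at the screening
    defaults for beta-value-style data (p<=0.001 Bonferroni, two of three
    comparisons, mean-difference floor 0.4)."""
    spec = CohortSpec(
        n_patients_per_class=n_per_class,
        modalities=("modality",),
        n_features=n_features,
        effect_size=effect_size,
        missing_rate=0.0,
        informative_fraction=0.1,
        seed=seed,
    )
    mm = generate_cohort(spec).modalities["modality"]
    selected = set(
        ttest_screen(
            mm,
            TTestSelectionConfig(
                alpha=0.001, bonferroni=True, required_comparisons=2,
                mean_diff_threshold=0.4,
            ),
        )
    )
    informative = set(mm.informative_features)
    noise = set(mm.feature_names) - informative
    return {
        "recall": len(selected & informative) / len(informative),
        "noise_rate": len(selected & noise) / len(noise),
        "n_informative": len(informative),
        "n_noise": len(noise),
    }


def cv_hygiene_study(n_cohorts: int = 100, seed: int = 0) -> dict:
    """Patient-wise disjointness and stratification balance over random cohorts."""
    rng = np.random.default_rng(seed)
    leaks = 0
    max_dev = 0.0
    for _ in range(n_cohorts):
        sizes = rng.integers(20, 60, size=3)
        labels = np.repeat(list(DEFAULT_CLASSES), sizes)
        rng.shuffle(labels)
        import pandas as pd

        series = pd.Series(labels, index=[f"P{i}" for i in range(len(labels))])
        k = int(rng.integers(2, 11))
        splits = stratified_patientwise_kfold(series, k, seed=int(rng.integers(0, 2**31 - 1)))
        for sp in splits:
            if set(sp.train_patients) & set(sp.test_patients):
                leaks += 1
            for cls in DEFAULT_CLASSES:
                n_cls = (series == cls).sum()
                in_fold = (series.loc[sp.test_patients] == cls).sum()
                # an even split puts n_cls/k patients of this class per fold
                max_dev = max(max_dev, abs(in_fold - n_cls / k))
    return {"leaks": leaks, "n_cohorts": n_cohorts, "max_class_deviation": max_dev}
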