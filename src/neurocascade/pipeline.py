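"""End-to-end orchestration of the five-step diagnostic pipeline:
simulate (or load) -> impute -> select variables -> train classifiers ->
optimise the two-stage cascade -> evaluate.

All randomness derives from one master seed; every stage artifact embeds the
seed and a hash of the configuration so reruns are auditable.  The heavy
knobs (epochs, nested-set size grid, sweep resolution) are configurable so
the same pipeline runs both at smoke-test scale and at full cohort scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from neurocascade import cascade as cascade_mod
from neurocascade import classifiers as clf_mod
from neurocascade import embedding, imputation
from neurocascade import variable_selection as vs
from neurocascade.dataset import CohortDataset
from neurocascade.metrics import confusion, diagnostic_report, roc_auc
from neurocascade.synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    inject_missingness,
    split_train_test,
)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    test_fraction: float = 0.2
    imputation_method: str = "knn"
    run_imputation_study: bool = False
    selection_alpha: float = 0.05
    selection_cv: int = 5
    selection_size_step: int = 4
    screener_spec: clf_mod.FCNSpec = field(default_factory=clf_mod.FCNSpec)
    battery_spec: clf_mod.CNNSpec | None = None
    train_config: clf_mod.TrainConfig = field(default_factory=clf_mod.TrainConfig)
    c_screen: float = 10.0
    c_battery: float = 180.0
    sweep_grid_points: int = 500
    f1_slack: float = 0.0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class Standardizer:
    """Column z-scoring with statistics frozen on the training rows."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        self.std[self.std == 0] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def _battery_input(
    dataset: CohortDataset, selected_battery_cols: np.ndarray
) -> np.ndarray:
    """Selected battery sub-scores in ranking-independent instrument order,
    followed by the demographics (the curve tail)."""
    demo = dataset.columns_with_role("demographic")
    cols = np.concatenate([selected_battery_cols, demo])
    return dataset.values[:, cols]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the report bundle."""
    seed = int(config.seed)
    stamp = {"seed": seed, "config_hash": config.config_hash()}
    bundle: dict = {"stamp": stamp}

    # -- stage 1: cohort ---------------------------------------------------
    cohort_cfg = config.cohort
    complete = generate_cohort(cohort_cfg)
    data = inject_missingness(complete, cohort_cfg)
    bundle["cohort"] = {
        "n_subjects": data.n_subjects,
        "n_positive": int(data.labels.sum()),
        "n_missing_subjects": int(data.missing_mask.any(axis=1).sum()),
    }

    # -- stage 2: imputation ----------------------------------------------
    if data.is_complete:
        completed = data  # nothing to do
        bundle["imputation"] = {"skipped": True}
    else:
        if config.run_imputation_study:
            study = imputation.run_imputation_study(data, seed=seed + 11)
            bundle["imputation_study"] = study.as_dict()
            method = study.winner or config.imputation_method
        else:
            method = config.imputation_method
        imputed = imputation.impute(
            data, method, **({"seed": seed + 11} if method == "mi" else {})
        )
        completed = data.with_values(imputed.values)
        bundle["imputation"] = {
            "skipped": False,
            "method": method,
            "n_cells_filled": int(imputed.imputed_mask.sum()),
        }

    train_ds, test_ds = split_train_test(completed, config.test_fraction, seed + 21)

    # -- stage 3: variable selection (battery sub-scores only) -------------
    battery_cols = train_ds.columns_with_role("battery_subscore")
    ranking = vs.rank_ensemble(
        train_ds.values[:, battery_cols],
        train_ds.labels,
        variable_names=[train_ds.variable_names[c] for c in battery_cols],
    )
    m = len(battery_cols)
    sizes = sorted(set(list(range(1, m + 1, config.selection_size_step)) + [m]))
    sets = vs.nested_set_evaluation(
        ranking,
        train_ds.values[:, battery_cols],
        train_ds.labels,
        cv=config.selection_cv,
        seed=seed + 31,
        sizes=sizes,
    )
    chosen = vs.select_minimal_set(sets, alpha=config.selection_alpha)
    selected_battery = battery_cols[ranking.final_order[: chosen.i]]
    bundle["selection"] = {
        "ranking": ranking.ordered_names(),
        "sets": [
            {"i": s.i, "auc_mean": s.auc_mean, "auc_std": s.auc_std, "delong_p": s.delong_p}
            for s in sets
        ],
        "selected_size": chosen.i,
        "selected": chosen.members,
    }

    # -- stage 4: classifiers ----------------------------------------------
    w_c = clf_mod.class_weight(train_ds.labels)

    scr_std = Standardizer().fit(train_ds.screener_matrix())
    screener = clf_mod.build_screener(config.screener_spec, seed=seed + 41)
    tc = config.train_config
    scr_cfg = clf_mod.TrainConfig(**{**asdict(tc), "seed": seed + 41})
    clf_mod.train(screener, scr_std.transform(train_ds.screener_matrix()), train_ds.labels, scr_cfg, w_c=w_c)

    bat_train = _battery_input(train_ds, selected_battery)
    bat_std = Standardizer().fit(bat_train)
    hmap = embedding.hilbert_coords(embedding.order_for(bat_train.shape[1]))
    spec = config.battery_spec or clf_mod.CNNSpec(grid_side=hmap.side)
    cnn = clf_mod.build_battery_cnn(spec, hmap, seed=seed + 42)
    grids = embedding.embed_matrix(bat_std.transform(bat_train), hmap)[:, None, :, :]
    cnn_cfg = clf_mod.TrainConfig(**{**asdict(tc), "seed": seed + 42})
    clf_mod.train(cnn, grids, train_ds.labels, cnn_cfg, w_c=w_c)

    # -- stage 5: cascade on the held-out test set -------------------------
    s1 = clf_mod.predict_scores(screener, scr_std.transform(test_ds.screener_matrix()))
    bat_test = _battery_input(test_ds, selected_battery)
    s2 = clf_mod.predict_scores(
        cnn, embedding.embed_matrix(bat_std.transform(bat_test), hmap)[:, None, :, :]
    )
    report = cascade_mod.run_cascade(
        s1,
        s2,
        test_ds.labels,
        c_screen=config.c_screen,
        c_battery=config.c_battery,
        grid_points=config.sweep_grid_points,
        f1_slack=config.f1_slack,
    )
    bundle["cascade"] = report.as_dict()

    # -- evaluation panels -------------------------------------------------
    def panel(pred, scores=None):
        rep = diagnostic_report(confusion(test_ds.labels, pred)).rounded()
        if scores is not None:
            rep["auc"] = round(roc_auc(scores, test_ds.labels), 4)
        return rep

    bundle["evaluation"] = {
        "screener_alone": panel((s1 >= 0.5).astype(int), s1),
        "battery_alone": panel((s2 >= 0.5).astype(int), s2),
        "two_stage": panel(report.decision.final_labels),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("cohort", "imputation", "selection", "cascade", "evaluation"):
            payload = {"stamp": stamp, name: bundle.get(name)}
            (out / f"{name}.json").write_text(json.dumps(payload, indent=2, default=str))
        data.to_csv(out / "cohort.csv")
    return bundle
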