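"""Configuration-driven orchestration of the full shape-classification
experiment: simulate (or load) a cohort, extract spectral features, run
cross-validation, learning curves, the permutation test, and
discriminative-map back-projection, with a provenance manifest.

The orchestrator only sequences library calls — every number in the result
bundle is reproducible by invoking the module operations directly with the
same seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .classifier import PCALDAClassifier
from .discriminative_map import backproject_axis
from .evaluation import learning_curve, permutation_test, run_cv, stratified_folds
from .spectral_features import FEATURE_SETS, feature_matrix
from .synthetic_data import CohortSpec, compute_bases, make_templates, simulate_cohort


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    feature_sets: tuple = ("hippocampal", "amygdalar", "combined")
    n_c: int = 70
    variance_fraction: float = 0.70
    cv_folds: int = 10
    n_orders: int = 500
    batch_size: int = 10
    n_permutations: int = 10000
    master_seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    run_learning_curve: bool = True
    run_permutation_test: bool = True
    test_fraction: float = 0.2  # held-out split for the learning curve

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the master seed."""
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["effect_structures"] = list(d["cohort"]["effect_structures"])
        d["feature_sets"] = list(d["feature_sets"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        coh = d.pop("cohort", {})
        if isinstance(coh, dict):
            coh.setdefault("effect_structures", None)
            if coh["effect_structures"] is None:
                coh.pop("effect_structures")
            else:
                coh["effect_structures"] = tuple(coh["effect_structures"])
            coh = CohortSpec(**coh)
        d["feature_sets"] = tuple(d.get("feature_sets", cls.feature_sets))
        return cls(cohort=coh, **d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(str(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment; returns a JSON-serializable result bundle.

    Stages: template/basis construction → cohort simulation → per-feature-
    set feature extraction → stratified k-fold CV → incremental learning
    curve on a held-out split → permutation test → discriminative maps.
    """
    t0 = time.time()
    manifest = {"config": config.to_dict(), "stage_seconds": {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    t = time.time()
    spec = config.cohort
    templates = make_templates(spec)
    bases = compute_bases(templates, max(config.n_c, spec.n_harmonics))
    manifest["stage_seconds"]["templates_and_bases"] = round(time.time() - t, 3)

    t = time.time()
    cohort = simulate_cohort(spec, bases, templates)
    y = cohort.labels
    manifest["stage_seconds"]["cohort"] = round(time.time() - t, 3)

    results: dict = {"feature_sets": {}, "manifest": manifest}
    for fset in config.feature_sets:
        if fset not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {fset!r}")
        fs_res: dict = {}
        t = time.time()
        X, ids, names = feature_matrix(cohort.fields, fset, bases, config.n_c)
        fs_res["n_subjects"], fs_res["n_features"] = X.shape

        cv = run_cv(
            X, y, k=config.cv_folds, seed=config.stage_seed(f"cv:{fset}"),
            variance_fraction=config.variance_fraction,
        )
        fs_res["cv"] = {
            "accuracy": cv.accuracy,
            "sensitivity": cv.sensitivity,
            "specificity": cv.specificity,
            "auc": cv.auc,
            "confusion": {"tp": cv.confusion.tp, "fn": cv.confusion.fn,
                          "tn": cv.confusion.tn, "fp": cv.confusion.fp},
            "per_subject": [
                {"subject_id": sid, "true": int(t_), "pred": int(p_),
                 "score": float(s_), "fold": int(f_)}
                for sid, t_, p_, s_, f_ in zip(
                    ids, y, cv.predictions, cv.scores, cv.fold_assignment
                )
            ],
        }

        if config.run_learning_curve:
            seed = config.stage_seed(f"lc:{fset}")
            folds = stratified_folds(
                y, max(2, int(round(1 / config.test_fraction))), seed
            )
            test = folds == 0
            lc = learning_curve(
                X[~test], y[~test], X[test], y[test],
                n_orders=config.n_orders, batch_size=config.batch_size,
                seed=seed, variance_fraction=config.variance_fraction,
            )
            fs_res["learning_curve"] = {
                "sizes": lc.sizes.tolist(),
                "mean_accuracy": [None if np.isnan(a) else float(a)
                                  for a in lc.mean_accuracy],
                "n_orders": lc.n_orders,
            }

        if config.run_permutation_test:
            pr = permutation_test(
                X, y, n_perm=config.n_permutations,
                seed=config.stage_seed(f"perm:{fset}"),
                k=config.cv_folds, variance_fraction=config.variance_fraction,
            )
            fs_res["permutation"] = {
                "observed_accuracy": pr.observed_accuracy,
                "p_value": pr.p_value,
                "n_permutations": pr.n_permutations,
            }

        clf = PCALDAClassifier(config.variance_fraction).fit(X, y)
        maps = backproject_axis(clf, bases, fset, config.n_c)
        fs_res["discriminative_maps"] = {
            tag: {"energy_share": m.energy_share,
                  "max_abs_vertex": int(np.argmax(np.abs(m.values)))}
            for tag, m in maps.items()
        }
        fs_res["pca_dimension"] = int(clf.pca_.d)
        manifest["stage_seconds"][f"feature_set:{fset}"] = round(time.time() - t, 3)
        results["feature_sets"][fset] = fs_res

    manifest["stage_seconds"]["total"] = round(time.time() - t0, 3)
    return results
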