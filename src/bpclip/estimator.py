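"""Two-stage calibration-free blood pressure regression.

Stage 1 regresses systolic (SBP) and mean (MBP) blood pressure on the 18
normalized oscillogram amplitudes with L1-penalized (LASSO) linear models,
the penalty chosen by inner cross-validation on the training subjects only.
Stage 2 regresses diastolic pressure (DBP) on the two stage-1 *predictions*
with ordinary least squares — since the mean-pressure reference is defined as
``MBP = SBP/3 + 2 DBP/3``, perfect stage-1 predictions imply the exact
identity ``DBP = 1.5 MBP - 0.5 SBP``, which stage 2 recovers.

Validation is leave-two-subjects-out: subjects are paired into disjoint
holdout folds, models are refitted from scratch on the remaining subjects for
every fold, and accuracy (MAE, bias, Bland-Altman limits of agreement) is
computed over held-out predictions only.

The modelling API follows the fit/results convention: build a
:class:`BPRegressionModel` from a feature table, call :meth:`fit` to obtain a
:class:`BPRegressionResults` carrying coefficients, chosen penalties and a
``summary()``; :func:`cross_validate` orchestrates the fold loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LinearRegression

N_FEATURES = 18
DEFAULT_ALPHAS = np.logspace(-4, 1, 30)


class FitError(RuntimeError):
    """Raised when a regression stage cannot be fitted."""


def compute_reference_mbp(sbp, dbp):
    """Mean blood pressure reference: SBP/3 + 2 DBP/3. Requires SBP > DBP."""
    sbp_a = np.asarray(sbp, dtype=float)
    dbp_a = np.asarray(dbp, dtype=float)
    if np.any(sbp_a <= dbp_a):
        raise ValueError("sbp must exceed dbp")
    out = sbp_a / 3.0 + 2.0 * dbp_a / 3.0
    if np.ndim(sbp) == 0:
        return float(out)
    return out


@dataclass
class SubjectRecord:
    """One screened subject: 18 features plus reference pressures."""

    subject_id: int
    features: np.ndarray
    sbp_ref: float
    dbp_ref: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(
                f"expected {N_FEATURES} features, got {self.features.shape}"
            )

    @property
    def mbp_ref(self) -> float:
        return compute_reference_mbp(self.sbp_ref, self.dbp_ref)


def _feature_columns(n: int = N_FEATURES) -> list[str]:
    return [f"amp_{i:02d}" for i in range(n)]


class BPRegressionModel:
    """Two-stage BP model bound to a cohort feature table.

    Parameters
    ----------
    features : (n_subjects, 18) array
        Normalized oscillogram amplitudes, each row in [0, 1].
    sbp_ref, dbp_ref : (n_subjects,) arrays
        Cuff reference pressures in mmHg.
    subject_ids : sequence, optional
        Stable identifiers; defaults to 0..n-1.
    """

    def __init__(self, features, sbp_ref, dbp_ref, subject_ids=None):
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.sbp_ref = np.asarray(sbp_ref, dtype=float)
        self.dbp_ref = np.asarray(dbp_ref, dtype=float)
        n = len(self.features)
        if self.features.shape[1] != N_FEATURES:
            raise ValueError(
                f"expected {N_FEATURES} features per subject, "
                f"got {self.features.shape[1]}"
            )
        if len(self.sbp_ref) != n or len(self.dbp_ref) != n:
            raise ValueError("features and references disagree in length")
        self.mbp_ref = compute_reference_mbp(self.sbp_ref, self.dbp_ref)
        self.subject_ids = (
            np.arange(n) if subject_ids is None else np.asarray(subject_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BPRegressionModel":
        """Build from a table with amp_00..amp_17, sbp_ref, dbp_ref columns."""
        cols = _feature_columns()
        missing = [c for c in cols + ["sbp_ref", "dbp_ref"] if c not in df]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        ids = df["subject_id"] if "subject_id" in df else None
        return cls(df[cols].to_numpy(), df["sbp_ref"], df["dbp_ref"], ids)

    def fit(
        self,
        alphas=None,
        inner_cv: int = 5,
        multi_target: bool = False,
        seed: int = 0,
    ) -> "BPRegressionResults":
        """Fit both stages on all bound subjects.

        ``multi_target=True`` fits SBP and MBP with a single shared penalty
        (chosen on SBP); the default fits two independent single-target LASSO
        models. The stage-2 OLS consumes the stage-1 predictions for the same
        training subjects (no nested holdout).
        """
        X = self.features
        n = len(X)
        if n < 4:
            raise FitError(f"need >= 4 training subjects, got {n}")
        if np.allclose(X.std(axis=0), 0.0):
            raise FitError("degenerate features: no variation across subjects")
        alphas = DEFAULT_ALPHAS if alphas is None else np.asarray(alphas)
        cv = min(inner_cv, n)
        sbp_lasso = LassoCV(
            alphas=alphas, cv=cv, max_iter=50_000, random_state=seed
        ).fit(X, self.sbp_ref)
        if multi_target:
            from sklearn.linear_model import Lasso

            mbp_lasso = Lasso(alpha=sbp_lasso.alpha_, max_iter=50_000).fit(
                X, self.mbp_ref
            )
            mbp_alpha = float(sbp_lasso.alpha_)
        else:
            mbp_lasso = LassoCV(
                alphas=alphas, cv=cv, max_iter=50_000, random_state=seed
            ).fit(X, self.mbp_ref)
            mbp_alpha = float(mbp_lasso.alpha_)

        sbp_hat = sbp_lasso.predict(X)
        mbp_hat = mbp_lasso.predict(X)
        Z = np.column_stack([sbp_hat, mbp_hat])
        Zc = Z - Z.mean(axis=0)
        if np.linalg.matrix_rank(Zc, tol=1e-8) < 2:
            if np.allclose(Zc, 0.0):
                # constant stage-1 predictions (e.g. penalty -> inf):
                # the DBP model degenerates to an intercept-only fit
                dbp_coef = np.zeros(2)
                dbp_intercept = float(np.mean(self.dbp_ref))
            else:
                raise FitError(
                    "collinear stage-1 predictions: cannot identify the DBP model"
                )
        else:
            dbp_ols = LinearRegression().fit(Z, self.dbp_ref)
            dbp_coef = dbp_ols.coef_.copy()
            dbp_intercept = float(dbp_ols.intercept_)
        return BPRegressionResults(
            model=self,
            sbp_coef=sbp_lasso.coef_.copy(),
            sbp_intercept=float(sbp_lasso.intercept_),
            sbp_alpha=float(sbp_lasso.alpha_),
            mbp_coef=mbp_lasso.coef_.copy(),
            mbp_intercept=float(mbp_lasso.intercept_),
            mbp_alpha=mbp_alpha,
            dbp_coef=dbp_coef,
            dbp_intercept=dbp_intercept,
        )


@dataclass
class BPRegressionResults:
    """Fitted two-stage model: coefficients, penalties, prediction, summary."""

    sbp_coef: np.ndarray
    sbp_intercept: float
    sbp_alpha: float
    mbp_coef: np.ndarray
    mbp_intercept: float
    mbp_alpha: float
    dbp_coef: np.ndarray  # on (sbp_hat, mbp_hat)
    dbp_intercept: float
    model: BPRegressionModel | None = None

    def predict(self, features) -> pd.DataFrame:
        """Predicted SBP/MBP/DBP (mmHg) for an (n, 18) feature array."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        sbp = X @ self.sbp_coef + self.sbp_intercept
        mbp = X @ self.mbp_coef + self.mbp_intercept
        dbp = (
            np.column_stack([sbp, mbp]) @ self.dbp_coef + self.dbp_intercept
        )
        return pd.DataFrame({"sbp_hat": sbp, "mbp_hat": mbp, "dbp_hat": dbp})

    def summary(self) -> str:
        lines = [
            "Two-stage blood pressure regression",
            "===================================",
            f"stage 1 (LASSO on {N_FEATURES} oscillogram amplitudes):",
            f"  SBP: alpha={self.sbp_alpha:.4g}, "
            f"{int(np.sum(self.sbp_coef != 0))} non-zero coefficients, "
            f"intercept={self.sbp_intercept:.2f}",
            f"  MBP: alpha={self.mbp_alpha:.4g}, "
            f"{int(np.sum(self.mbp_coef != 0))} non-zero coefficients, "
            f"intercept={self.mbp_intercept:.2f}",
            "stage 2 (OLS on stage-1 predictions):",
            f"  DBP = {self.dbp_coef[0]:+.3f} * SBP_hat "
            f"{self.dbp_coef[1]:+.3f} * MBP_hat "
            f"{self.dbp_intercept:+.2f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sbp": {
                "coef": self.sbp_coef.tolist(),
                "intercept": self.sbp_intercept,
                "alpha": self.sbp_alpha,
            },
            "mbp": {
                "coef": self.mbp_coef.tolist(),
                "intercept": self.mbp_intercept,
                "alpha": self.mbp_alpha,
            },
            "dbp": {
                "coef": self.dbp_coef.tolist(),
                "intercept": self.dbp_intercept,
            },
        }

    def save(self, path) -> None:
        """Serialize the fitted coefficients as JSON."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "BPRegressionResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            sbp_coef=np.asarray(d["sbp"]["coef"]),
            sbp_intercept=d["sbp"]["intercept"],
            sbp_alpha=d["sbp"]["alpha"],
            mbp_coef=np.asarray(d["mbp"]["coef"]),
            mbp_intercept=d["mbp"]["intercept"],
            mbp_alpha=d["mbp"]["alpha"],
            dbp_coef=np.asarray(d["dbp"]["coef"]),
            dbp_intercept=d["dbp"]["intercept"],
        )


def make_folds(subject_ids, seed: int = 0) -> list[tuple]:
    """Pair subjects into disjoint leave-two-out holdout folds.

    Pairing is a seeded random permutation of the *sorted* roster, so the
    folds depend only on the set of identifiers and the seed, not on input
    order. An odd roster raises: the caller must decide which subject to
    drop.
    """
    ids = sorted(np.asarray(subject_ids).tolist())
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    if len(ids) % 2 != 0:
        raise ValueError(
            f"need an even number of subjects for leave-two-out folds, got "
            f"{len(ids)}; drop or add one explicitly"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return [tuple(shuffled[i : i + 2]) for i in range(0, len(shuffled), 2)]


def bland_altman(pred, ref) -> dict:
    """Bias and 95 % limits of agreement of predictions against references."""
    err = np.asarray(pred, dtype=float) - np.asarray(ref, dtype=float)
    bias = float(err.mean())
    sd = float(err.std(ddof=1)) if len(err) > 1 else 0.0
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_error": sd,
    }


def accuracy_report(predictions: pd.DataFrame) -> dict:
    """Per-target MAE +/- sd of absolute error, bias, Bland-Altman limits.

    ``predictions`` must hold sbp_hat/mbp_hat/dbp_hat and the matching
    *_ref columns (held-out predictions only).
    """
    report = {}
    for target in ("sbp", "mbp", "dbp"):
        pred = predictions[f"{target}_hat"].to_numpy()
        ref = predictions[f"{target}_ref"].to_numpy()
        abs_err = np.abs(pred - ref)
        ba = bland_altman(pred, ref)
        r = (
            float(np.corrcoef(pred, ref)[0, 1])
            if len(pred) > 1 and np.std(ref) > 0 and np.std(pred) > 0
            else float("nan")
        )
        report[target] = {
            "mae": float(abs_err.mean()),
            "mae_sd": float(abs_err.std(ddof=1)) if len(abs_err) > 1 else 0.0,
            "pearson_r": r,
            **ba,
        }
    return report


@dataclass
class CrossValidationResult:
    """Held-out predictions plus the derived agreement statistics."""

    predictions: pd.DataFrame
    report: dict
    folds: list[tuple]
    seed: int
    fold_results: list[BPRegressionResults] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Leave-two-subjects-out validation "
            f"({len(self.folds)}-fold, {len(self.predictions)} subjects, "
            f"fold seed {self.seed})",
            "-" * 66,
            f"{'target':<8}{'MAE (mmHg)':>14}{'bias':>8}"
            f"{'LoA low':>10}{'LoA high':>10}{'r':>8}",
        ]
        for target in ("sbp", "mbp", "dbp"):
            s = self.report[target]
            lines.append(
                f"{target.upper():<8}"
                f"{s['mae']:>7.2f} ± {s['mae_sd']:<5.2f}"
                f"{s['bias']:>7.2f}"
                f"{s['loa_low']:>10.2f}{s['loa_high']:>10.2f}"
                f"{s['pearson_r']:>8.3f}"
            )
        return "\n".join(lines)


def cross_validate(
    model: BPRegressionModel,
    seed: int = 0,
    alphas=None,
    inner_cv: int = 5,
    multi_target: bool = False,
) -> CrossValidationResult:
    """Leave-two-subjects-out cross-validation of the two-stage model.

    For every fold, both stages are refitted on the training subjects only
    and the two held-out subjects are predicted by that fold's model. Every
    fold must retain at least 4 training subjects.
    """
    ids = model.subject_ids
    folds = make_folds(ids, seed=seed)
    order = {sid: i for i, sid in enumerate(ids.tolist())}
    rows = []
    fold_results = []
    for fold_id, holdout in enumerate(folds):
        test_idx = np.array([order[s] for s in holdout])
        train_mask = np.ones(len(ids), dtype=bool)
        train_mask[test_idx] = False
        if train_mask.sum() < 4:
            raise FitError(
                f"fold {fold_id} leaves only {int(train_mask.sum())} training "
                "subjects; need >= 4"
            )
        sub = BPRegressionModel(
            model.features[train_mask],
            model.sbp_ref[train_mask],
            model.dbp_ref[train_mask],
            subject_ids=ids[train_mask],
        )
        res = sub.fit(
            alphas=alphas, inner_cv=inner_cv, multi_target=multi_target, seed=seed
        )
        fold_results.append(res)
        pred = res.predict(model.features[test_idx])
        for j, sid in zip(range(len(test_idx)), holdout):
            i = test_idx[j]
            rows.append(
                {
                    "subject_id": sid,
                    "fold": fold_id,
                    "sbp_hat": pred["sbp_hat"].iloc[j],
                    "mbp_hat": pred["mbp_hat"].iloc[j],
                    "dbp_hat": pred["dbp_hat"].iloc[j],
                    "sbp_ref": model.sbp_ref[i],
                    "mbp_ref": model.mbp_ref[i],
                    "dbp_ref": model.dbp_ref[i],
                }
            )
    predictions = (
        pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
    )
    return CrossValidationResult(
        predictions=predictions,
        report=accuracy_report(predictions),
        folds=folds,
        seed=seed,
        fold_results=fold_results,
    )


def plot_bland_altman(predictions: pd.DataFrame, target: str = "sbp", ax=None):
    """Bland-Altman plot (mean vs difference) for one target."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pred = predictions[f"{target}_hat"].to_numpy()
    ref = predictions[f"{target}_ref"].to_numpy()
    ba = bland_altman(pred, ref)
    ax.scatter((pred + ref) / 2.0, pred - ref, s=18, alpha=0.8)
    for y, style in ((ba["bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, color="grey", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of predicted and reference {target.upper()} (mmHg)")
    ax.set_ylabel("predicted - reference (mmHg)")
    ax.set_title(
        f"{target.upper()}: bias {ba['bias']:.2f} mmHg, "
        f"LoA [{ba['loa_low']:.1f}, {ba['loa_high']:.1f}]"
    )
    return ax
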