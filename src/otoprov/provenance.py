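"""Local/nonlocal classification of fish from stage-resolved otolith isotopes.

Fish captured in the Sea of Japan / East China Sea (SJ-ECS) coastal system
are split into "locals" (grew up inside the system) and "nonlocals" (grew up
elsewhere) in two steps:

1. **Threshold rule** — within each year-class, the reference set (age-0 fish
   from the SJ-ECS plus age-1 fish from West Kyushu, both groups showing the
   marked ontogenetic d18O decrease typical of local seasonal warming) defines
   a cutoff equal to its *highest* juvenile-stage d18O.  SJ-ECS fish at or
   below the cutoff are locals, above it nonlocals.  Age-0 SJ-ECS fish whose
   juvenile portion was not milled are assigned local (they were captured in
   the system during their first summer-autumn).

2. **Linear discriminant** — age-1 fish from the Oki Islands / Noto Peninsula
   lacking a juvenile measurement are classified by a pooled-covariance linear
   discriminant trained on larval d18O, larval d13C and otolith radius at
   60 dph of the threshold-labeled locals and nonlocals of all year-classes,
   with accuracy estimated by leave-one-out cross-validation.

Fish from the subarctic offshore Pacific form their own fixed group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from otoprov.data_io import Label, Region, SJ_ECS_REGIONS

#: Features entering the discriminant and the multivariate group comparison.
LDA_FEATURES = ["larval_d18O", "larval_d13C", "radius_at_60dph_um"]


def merge_stage_with_samples(stage_values: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Join stage values to sample metadata (region, age, year-class, date)."""
    meta = samples[["fish_id", "region", "age", "year_class", "capture_date"]]
    return stage_values.merge(meta, on="fish_id", how="inner", validate="1:1")


# ---------------------------------------------------------------------------
# Threshold rule

@dataclass(frozen=True)
class ThresholdRule:
    """Per-year-class juvenile-d18O cutoff separating locals from nonlocals."""

    year_class: int
    threshold_permil: float
    n_reference: int

    def __post_init__(self) -> None:
        if self.n_reference < 1:
            raise ValueError("threshold rule needs at least one reference fish")


class EmptyReferenceError(ValueError):
    """No reference fish available for a year-class."""


def _reference_mask(df: pd.DataFrame) -> pd.Series:
    """Reference set: age-0 fish in SJ-ECS regions and age-1 fish around West
    Kyushu, with a juvenile-stage measurement.  Pacific-offshore fish never
    enter the reference set."""
    sj_ecs = df["region"].isin([r.value for r in SJ_ECS_REGIONS])
    age0 = sj_ecs & (df["age"] == 0)
    age1_wk = (df["region"] == Region.WestKyushu.value) & (df["age"] == 1)
    return (age0 | age1_wk) & df["juvenile_d18O"].notna()


def compute_threshold(df: pd.DataFrame, year_class: int) -> ThresholdRule:
    """Threshold = maximum juvenile-stage d18O over the year-class's reference set."""
    ref = df[_reference_mask(df) & (df["year_class"] == year_class)]
    if ref.empty:
        raise EmptyReferenceError(
            f"year-class {year_class}: no reference fish with juvenile d18O"
        )
    return ThresholdRule(
        year_class=int(year_class),
        threshold_permil=float(ref["juvenile_d18O"].max()),
        n_reference=int(len(ref)),
    )


def compute_thresholds(df: pd.DataFrame) -> dict[int, ThresholdRule]:
    """One threshold rule per year-class present among SJ-ECS fish."""
    sj = df[df["region"].isin([r.value for r in SJ_ECS_REGIONS])]
    return {
        int(yc): compute_threshold(df, int(yc))
        for yc in sorted(sj["year_class"].unique())
    }


def assign_by_threshold(
    df: pd.DataFrame, rules: Mapping[int, ThresholdRule]
) -> pd.DataFrame:
    """Apply the threshold rule; returns a copy with ``label`` and ``label_source``.

    * Pacific-offshore fish -> ``pacific_offshore`` (source ``fixed``).
    * SJ-ECS fish with a juvenile value: at-or-below threshold -> ``local``,
      above -> ``nonlocal`` (source ``threshold``).
    * Age-0 SJ-ECS fish without a juvenile value -> ``local`` (source
      ``fixed``): they were captured in the system in their first year.
    * Age-1 SJ-ECS fish without a juvenile value -> ``unclassified`` (left for
      the discriminant step).

    Idempotent and independent of record order.
    """
    out = df.copy()
    out["label"] = Label.unclassified.value
    out["label_source"] = ""
    is_pac = out["region"] == Region.PacificOffshore.value
    out.loc[is_pac, "label"] = Label.pacific_offshore.value
    out.loc[is_pac, "label_source"] = "fixed"

    sj = out["region"].isin([r.value for r in SJ_ECS_REGIONS])
    has_juv = out["juvenile_d18O"].notna()

    missing = sorted(set(out.loc[sj & has_juv, "year_class"].astype(int)) - set(rules))
    if missing:
        raise KeyError(f"no threshold rule for year-class(es) {missing}")

    for yc, rule in rules.items():
        in_yc = sj & has_juv & (out["year_class"] == yc)
        below = out["juvenile_d18O"] <= rule.threshold_permil
        out.loc[in_yc & below, "label"] = Label.local.value
        out.loc[in_yc & ~below, "label"] = Label.nonlocal_.value
        out.loc[in_yc, "label_source"] = "threshold"

    age0_no_juv = sj & ~has_juv & (out["age"] == 0)
    out.loc[age0_no_juv, "label"] = Label.local.value
    out.loc[age0_no_juv, "label_source"] = "fixed"
    return out


# ---------------------------------------------------------------------------
# Linear discriminant

class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-class covariance is singular; check features for
    collinearity or duplicated columns."""


@dataclass
class DiscriminantModel:
    """Pooled-covariance linear discriminant over two provenance classes.

    The score of class ``c`` at feature vector ``x`` is
    ``ln(prior_c) + mu_c' S^-1 x - 0.5 mu_c' S^-1 mu_c`` with ``S`` the pooled
    within-class covariance; classification maximizes the score, with exact
    ties resolved to ``local`` for determinism.
    """

    classes: tuple[str, str]
    means: np.ndarray  # (2, p)
    pooled_cov: np.ndarray  # (p, p)
    priors: np.ndarray  # (2,)
    features: Sequence[str] = field(default_factory=lambda: tuple(LDA_FEATURES))
    coef: np.ndarray = field(init=False)  # (2, p)
    intercept: np.ndarray = field(init=False)  # (2,)

    def __post_init__(self) -> None:
        try:
            cov_inv = np.linalg.inv(self.pooled_cov)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(str(exc)) from exc
        if np.linalg.cond(self.pooled_cov) > 1e12:
            raise SingularCovarianceError(
                "pooled covariance is numerically singular; check features"
            )
        self.coef = self.means @ cov_inv
        self.intercept = (
            -0.5 * np.einsum("ij,ij->i", self.coef, self.means) + np.log(self.priors)
        )

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        # tie -> the first class (local) for determinism
        idx = np.where(s[:, 0] >= s[:, 1], 0, 1)
        return np.asarray(self.classes)[idx]


def learning_mask(df: pd.DataFrame) -> pd.Series:
    """Fish eligible as discriminant learning data: threshold-labeled locals or
    nonlocals with complete features, a juvenile measurement and an
    increment-based age reading (fish lacking either are excluded from the
    learning set and the multivariate comparison)."""
    labeled = df["label"].isin([Label.local.value, Label.nonlocal_.value])
    complete = df[LDA_FEATURES].notna().all(axis=1)
    has_juv = df["juvenile_d18O"].notna()
    has_incr = (
        df["has_increment_reading"]
        if "has_increment_reading" in df.columns
        else pd.Series(True, index=df.index)
    )
    return labeled & complete & has_juv & has_incr.astype(bool)


def fit_lda(df: pd.DataFrame, features: Sequence[str] = LDA_FEATURES) -> DiscriminantModel:
    """Fit the discriminant on the learning set with proportional priors and
    unstandardized features (linear discriminants are affine-equivariant)."""
    learn = df[learning_mask(df)]
    classes = (Label.local.value, Label.nonlocal_.value)
    X, mus, ns = [], [], []
    pooled = np.zeros((len(features), len(features)))
    for c in classes:
        Xc = learn.loc[learn["label"] == c, list(features)].to_numpy(dtype=float)
        if len(Xc) < 2:
            raise ValueError(f"class {c!r}: need >= 2 learning fish, got {len(Xc)}")
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        pooled += dev.T @ dev
        mus.append(mu)
        ns.append(len(Xc))
        X.append(Xc)
    n = sum(ns)
    pooled /= n - len(classes)
    return DiscriminantModel(
        classes=classes,
        means=np.array(mus),
        pooled_cov=pooled,
        priors=np.array(ns, dtype=float) / n,
        features=tuple(features),
    )


@dataclass
class LoocvReport:
    """Leave-one-out cross-validation accuracy of the discriminant.

    ``per_predicted`` counts, for each *predicted* class, how many predictions
    were made and how many of those were correct (the precision structure of a
    confusion matrix read column-wise)."""

    n: int
    n_correct: int
    per_predicted: pd.DataFrame  # predicted_label, n_predicted, n_correct, precision
    n_skipped: int = 0

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n if self.n else float("nan")


def loocv(df: pd.DataFrame, features: Sequence[str] = LDA_FEATURES) -> LoocvReport:
    """Refit the discriminant n times, each excluding one fish; priors are
    re-estimated per fold from the fold's training labels.  A fold whose
    removal would empty a class (the class has a single member) is skipped
    with a warning."""
    learn = df[learning_mask(df)].reset_index(drop=True)
    labels = learn["label"].to_numpy()
    X = learn[list(features)].to_numpy(dtype=float)
    preds = np.full(len(learn), None, dtype=object)
    n_skipped = 0
    class_counts = pd.Series(labels).value_counts()
    for i in range(len(learn)):
        if class_counts[labels[i]] <= 2:
            # removal leaves < 2 members: covariance of that class undefined
            n_skipped += 1
            warnings.warn(f"LOOCV: fold {i} skipped (class too small)", stacklevel=2)
            continue
        fold = learn.drop(index=i)
        model = fit_lda(fold, features)
        preds[i] = model.predict(X[i : i + 1])[0]
    kept = preds != None  # noqa: E711
    correct = np.array([p == t for p, t in zip(preds[kept], labels[kept])])
    rows = []
    for c in (Label.local.value, Label.nonlocal_.value):
        sel = preds[kept] == c
        n_pred = int(sel.sum())
        n_ok = int((correct & sel).sum())
        rows.append(
            {
                "predicted_label": c,
                "n_predicted": n_pred,
                "n_correct": n_ok,
                "precision": n_ok / n_pred if n_pred else float("nan"),
            }
        )
    return LoocvReport(
        n=int(kept.sum()),
        n_correct=int(correct.sum()),
        per_predicted=pd.DataFrame(rows),
        n_skipped=n_skipped,
    )


def classify_unlabeled(
    model: DiscriminantModel, df: pd.DataFrame
) -> pd.DataFrame:
    """Label the still-unclassified fish with the discriminant.

    Threshold/fixed labels are never overwritten.  Unclassified fish missing a
    feature are skipped with a warning.  Adds per-class linear scores for the
    relabeled fish.
    """
    out = df.copy()
    if "lda_score_local" not in out.columns:
        out["lda_score_local"] = np.nan
        out["lda_score_nonlocal"] = np.nan
    todo = out["label"] == Label.unclassified.value
    complete = out[list(model.features)].notna().all(axis=1)
    skipped = out.loc[todo & ~complete, "fish_id"]
    for fid in skipped:
        warnings.warn(f"fish {fid}: missing feature, left unclassified", stacklevel=2)
    sel = todo & complete
    if sel.any():
        X = out.loc[sel, list(model.features)].to_numpy(dtype=float)
        s = model.scores(X)
        out.loc[sel, "label"] = model.predict(X)
        out.loc[sel, "label_source"] = "lda"
        out.loc[sel, "lda_score_local"] = s[:, 0]
        out.loc[sel, "lda_score_nonlocal"] = s[:, 1]
    return out


# ---------------------------------------------------------------------------
# Proportion tables

def proportions_by_group(
    df: pd.DataFrame, group_keys: Sequence[str] = ("region", "year_class")
) -> pd.DataFrame:
    """Counts and percent-nonlocal per group.

    ``group_keys`` is a subset of {"region", "year_class", "capture_month"}.
    ``pct_nonlocal`` = 100 * n_nonlocal / (n_local + n_nonlocal); undefined
    (NaN, flagged) for empty groups.  Discriminant-derived labels are counted
    separately in ``n_lda_labeled`` so downstream plots can shade them.
    """
    allowed = {"region", "year_class", "capture_month"}
    if not set(group_keys) <= allowed:
        raise ValueError(f"group keys must be a subset of {sorted(allowed)}")
    work = df.copy()
    if "capture_month" in group_keys:
        work["capture_month"] = pd.to_datetime(work["capture_date"]).dt.month
    rows = []
    for key, g in work.groupby(list(group_keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n_local = int((g["label"] == Label.local.value).sum())
        n_nonlocal = int((g["label"] == Label.nonlocal_.value).sum())
        n_uncl = int((g["label"] == Label.unclassified.value).sum())
        n_lda = int((g["label_source"] == "lda").sum()) if "label_source" in g else 0
        denom = n_local + n_nonlocal
        rows.append(
            dict(zip(group_keys, key))
            | {
                "n_local": n_local,
                "n_nonlocal": n_nonlocal,
                "n_unclassified": n_uncl,
                "n_lda_labeled": n_lda,
                "pct_nonlocal": 100.0 * n_nonlocal / denom if denom else np.nan,
                "pct_defined": denom > 0,
            }
        )
    return pd.DataFrame(rows)
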