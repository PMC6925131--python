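"""Sample-level breakome profiling: gene-strand break-density matrices,
PCA clustering, the 8-feature sample vector, and the age models.

The break density of a (gene, strand) cell is

    count / (gene length in kb * total breaks in sample) * 1e6,

i.e. breaks per kilobase per million sample breaks, which makes rows
invariant under read duplication.  The age classifier is a maximum
likelihood logistic regression (young/old labels); reported metrics are
training-set accuracy at threshold 0.5, ROC/AUC and McFadden's pseudo-R^2
(1 - lnL_model / lnL_null).  The age regressor is ordinary least squares;
its headline number is the Pearson correlation between fitted and
chronological age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve

from .breakcall import BreakSet
from .stats import element_enrichment, conservation_profile
from .tracks import SignalTrack

__all__ = [
    "AnnotationBundle",
    "SampleFeatures",
    "ClassifierReport",
    "RegressorReport",
    "gene_density_matrix",
    "pca_embed",
    "sample_features",
    "fit_age_classifier",
    "fit_age_regressor",
]

Interval = tuple[str, int, int]


def gene_density_matrix(
    samples: Mapping[str, BreakSet],
    genes: Sequence[tuple[str, int, int, str, str]],
) -> pd.DataFrame:
    """Samples x (gene, strand) break-density matrix.

    A break contributes to a (gene, strand) cell iff it lies inside the
    gene interval and its broken strand matches the cell's strand.
    Zero-length genes are excluded with a warning.
    """
    kept = []
    for g in genes:
        if g[2] - g[1] <= 0:
            warnings.warn(f"gene {g[4]} has zero length; excluded")
        else:
            kept.append(g)
    columns = pd.MultiIndex.from_tuples(
        [(g[4], s) for g in kept for s in "+-"], names=["gene", "strand"]
    )
    data = np.zeros((len(samples), len(columns)))
    sample_ids = list(samples)
    for i, sid in enumerate(sample_ids):
        bs = samples[sid]
        total = len(bs)
        if total == 0:
            raise ValueError(f"sample {sid} has no breaks")
        for j, (gc, gs, ge, _, gname) in enumerate(kept):
            kb = (ge - gs) / 1000.0
            for js, strand in enumerate("+-"):
                count = sum(
                    1 for (c, p, s) in bs.calls
                    if c == gc and gs <= p < ge and s == strand
                )
                data[i, 2 * j + js] = count / (kb * total) * 1e6
    return pd.DataFrame(data, index=sample_ids, columns=columns)


def pca_embed(
    matrix: pd.DataFrame, n_components: int = 2, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component embedding of samples.

    Features are centered (and variance-scaled when ``scale``) before the
    eigendecomposition; components come ordered by decreasing explained
    variance.  Requesting more components than samples allow truncates
    with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components truncated from {n_components} to {max_comp}"
        )
        n_components = max_comp
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    out = pd.DataFrame(
        coords, index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return out, pca.explained_variance_ratio_


@dataclass
class AnnotationBundle:
    """Everything sample_features needs: element interval sets, the
    enrichment background, a basewise conservation track, and the name of
    the mitochondrial contig."""

    exons: list[Interval]
    introns: list[Interval]
    promoters: list[Interval]
    insulators: list[Interval]
    enhancers: list[Interval]
    background: list[Interval]
    phylop: SignalTrack
    chrM: str = "chrM"


FEATURE_NAMES = [
    "or_exons", "or_introns", "or_promoters", "or_insulators", "or_enhancers",
    "phylop_positive", "phylop_negative_abs", "chrM_fraction",
]


@dataclass
class SampleFeatures:
    or_exons: float
    or_introns: float
    or_promoters: float
    or_insulators: float
    or_enhancers: float
    phylop_positive: float
    phylop_negative_abs: float
    chrM_fraction: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def sample_features(breaks: BreakSet, annotations: AnnotationBundle) -> SampleFeatures:
    """The 8-feature sample vector: element enrichment odds ratios, mean
    positive / |negative| conservation in +/-20 bp windows, and the
    fraction of breaks on the mitochondrial contig."""
    for name in ("exons", "introns", "promoters", "insulators", "enhancers",
                 "background"):
        if not getattr(annotations, name):
            raise ValueError(f"annotation bundle is missing {name}")
    ors = {}
    for name in ("exons", "introns", "promoters", "insulators", "enhancers"):
        res = element_enrichment(breaks, getattr(annotations, name),
                                 annotations.background)
        ors[name] = res.odds_ratio
    cons = conservation_profile(breaks, annotations.phylop, windows=(20,))[20]
    chrm = sum(1 for c, _, _ in breaks.calls if c == annotations.chrM)
    return SampleFeatures(
        or_exons=ors["exons"],
        or_introns=ors["introns"],
        or_promoters=ors["promoters"],
        or_insulators=ors["insulators"],
        or_enhancers=ors["enhancers"],
        phylop_positive=cons["mean_positive"],
        phylop_negative_abs=cons["mean_negative_abs"],
        chrM_fraction=chrm / len(breaks),
    )


@dataclass
class ClassifierReport:
    coefficients: dict[str, float]
    accuracy: float
    auc: float
    mcfadden_r2: float
    roc_points: list[tuple[float, float]]
    converged: bool
    separation_flag: bool
    fitted_probabilities: np.ndarray
    cv_auc: float | None = None
    cv_accuracy: float | None = None


@dataclass
class RegressorReport:
    coefficients: dict[str, float]
    fitted_ages: np.ndarray
    pearson_r: float
    model_p_value: float
    rank_deficient: bool = False


def _feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features.astype(float)
    rows = [f.as_vector() for f in features]
    return pd.DataFrame(rows, columns=FEATURE_NAMES)


def _fit_logit(y: np.ndarray, Xc: pd.DataFrame):
    try:
        return sm.Logit(y, Xc).fit(disp=0, maxiter=200), False
    except Exception:  # perfect separation can abort Newton iterations
        return sm.Logit(y, Xc).fit(disp=0, maxiter=500, method="bfgs"), True


def fit_age_classifier(
    features, labels: Sequence[int | str | bool],
    cv: int | None = None, seed: int = 0,
) -> ClassifierReport:
    """Maximum-likelihood logistic regression of old (1) vs young (0).

    Labels may be 0/1 or a pair of strings (sorted; the later one is
    coded 1).  Headline metrics are training-set by default; ``cv`` adds
    stratified k-fold out-of-fold AUC/accuracy (the honest numbers for
    small samples, where in-sample AUC is optimistic).  Perfect
    separation is flagged and the diverging coefficients are still
    reported with a convergence note.
    """
    X = _feature_frame(features)
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        classes = sorted(set(y))
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        y = (y == classes[1]).astype(int)
    y = y.astype(int)
    if len(set(y)) != 2:
        raise ValueError("both classes must be present")
    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res, separation = _fit_logit(y, Xc)
        for w in caught:
            if "separation" in str(w.message).lower() or \
               "convergence" in str(w.message).lower():
                separation = separation or "separation" in str(w.message).lower()
                converged = False
    probs = np.asarray(res.predict(Xc))
    acc = float(((probs >= 0.5).astype(int) == y).mean())
    fpr, tpr, _ = roc_curve(y, probs)
    auc = float(np.trapezoid(tpr, fpr))
    llnull = float(res.llnull)
    mcf = 0.0 if llnull == 0 else float(1.0 - res.llf / llnull)
    cv_auc = cv_acc = None
    if cv is not None:
        from sklearn.model_selection import StratifiedKFold

        oof = np.full(len(y), np.nan)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for train, test in skf.split(Xc, y):
                fold_res, _ = _fit_logit(y[train], Xc.iloc[train])
                oof[test] = np.asarray(fold_res.predict(Xc.iloc[test]))
        fpr_cv, tpr_cv, _ = roc_curve(y, oof)
        cv_auc = float(np.trapezoid(tpr_cv, fpr_cv))
        cv_acc = float(((oof >= 0.5).astype(int) == y).mean())
    return ClassifierReport(
        coefficients=dict(zip(Xc.columns, np.asarray(res.params))),
        accuracy=acc,
        auc=auc,
        mcfadden_r2=mcf,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        converged=converged and not separation,
        separation_flag=separation,
        fitted_probabilities=probs,
        cv_auc=cv_auc,
        cv_accuracy=cv_acc,
    )


def fit_age_regressor(features, ages: Sequence[float]) -> RegressorReport:
    """OLS of chronological age on the breakome features; reports the
    fitted-vs-true Pearson r and the overall model F-test p-value.
    Rank-deficient designs are reported and fit by pseudo-inverse."""
    X = _feature_frame(features)
    y = np.asarray(ages, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("need >= 2 distinct ages")
    Xc = sm.add_constant(X, has_constant="add")
    rank_def = np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]
    res = sm.OLS(y, Xc).fit()  # statsmodels uses pinv, handles rank deficiency
    fitted = np.asarray(res.fittedvalues)
    if np.allclose(fitted, fitted[0]):
        r = 0.0
    else:
        r = float(sps.pearsonr(fitted, y)[0])
    return RegressorReport(
        coefficients=dict(zip(Xc.columns, np.asarray(res.params))),
        fitted_ages=fitted,
        pearson_r=r,
        model_p_value=float(res.f_pvalue) if not math.isnan(res.f_pvalue) else 1.0,
        rank_deficient=bool(rank_def),
    )
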