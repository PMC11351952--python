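"""Repeated external cross-validation, permutation null and KS significance.

The significance framework builds OPLS-DA models from many random splits of
the data: each repetition partitions the samples into stratified external
folds; per fold, scaling statistics are computed on the training split only,
the number of orthogonal components is chosen by internal cross-validation
inside the training split, a model is fitted and scored on the held-out
fold.  With the defaults (8 external folds × 100 repetitions) this yields
exactly 800 models per pairwise comparison.  The identical scheme run on
label-shuffled data (one shuffle per repetition) gives the permutation-null
accuracy distribution, whose mean sits near 50%; a one-sided two-sample
Kolmogorov–Smirnov test between true and permuted accuracies decides
significance at p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .latent import OplsModel, opls_path
from .preproc import BinMatrix, apply_pareto, pareto_stats

__all__ = [
    "CvConfig",
    "CvResult",
    "ValidationReport",
    "COMPARISONS",
    "stratified_folds",
    "repeated_external_cv",
    "permutation_null",
    "ks_significance",
    "run_all_pairwise",
]

#: The four pairwise group comparisons of a two-factor design:
#: diet within each genotype, then genotype within each diet.
COMPARISONS = (
    ("WT/CD", "WT/WD"),
    ("KO/CD", "KO/WD"),
    ("WT/CD", "KO/CD"),
    ("WT/WD", "KO/WD"),
)


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation scheme parameters (defaults: 8 × 100 = 800 models)."""

    external_folds: int = 8
    repetitions: int = 100
    internal_folds: int = 7
    max_orth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.external_folds < 2 or self.internal_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.max_orth < 0:
            raise ValueError("max_orth must be >= 0")

    @property
    def n_models(self) -> int:
        return self.external_folds * self.repetitions


@dataclass
class CvResult:
    """One arm (true or permuted) of the validation scheme."""

    records: pd.DataFrame  # one row per model
    accuracies: np.ndarray
    vip_mean: np.ndarray  # per-bin mean VIP over all models
    models: list[OplsModel] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.records["sensitivity"].to_numpy()))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.records["specificity"].to_numpy()))


@dataclass
class ValidationReport:
    """True + permuted arms of one pairwise comparison with the KS call."""

    comparison: str
    true: CvResult
    perm: CvResult
    ks_statistic: float
    ks_p: float
    significant: bool

    @property
    def true_accuracies(self) -> np.ndarray:
        return self.true.accuracies

    @property
    def perm_accuracies(self) -> np.ndarray:
        return self.perm.accuracies

    @property
    def records(self) -> pd.DataFrame:
        t = self.true.records.assign(arm="true")
        p = self.perm.records.assign(arm="permuted")
        return pd.concat([t, p], ignore_index=True)

    def summary(self) -> dict:
        return {
            "comparison": self.comparison,
            "n_models": int(len(self.true.records)),
            "accuracy": self.true.mean_accuracy,
            "sensitivity": self.true.mean_sensitivity,
            "specificity": self.true.mean_specificity,
            "permuted_accuracy": self.perm.mean_accuracy,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "significant": self.significant,
        }


def stratified_folds(ypos: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign samples to folds, spreading each class round-robin.

    Members of each class are shuffled and dealt to folds ``(j + offset) %
    n_folds`` with a random per-class offset, so fold class counts never
    differ by more than one.
    """
    fold = np.empty(ypos.size, dtype=int)
    for cls in (True, False):
        idx = np.nonzero(ypos == cls)[0]
        idx = rng.permutation(idx)
        offset = int(rng.integers(n_folds))
        fold[idx] = (np.arange(idx.size) + offset) % n_folds
    return fold


def _valid_partition(fold: np.ndarray, ypos: np.ndarray, n_folds: int) -> bool:
    """Every fold non-empty and every training split two-class."""
    if np.unique(fold).size != n_folds:
        return False
    for cls in (True, False):
        if np.unique(fold[ypos == cls]).size < 2:
            return False
    return True


def _draw_partition(ypos, n_folds, rng, retries: int = 10) -> np.ndarray:
    for _ in range(retries):
        fold = stratified_folds(ypos, n_folds, rng)
        if _valid_partition(fold, ypos, n_folds):
            return fold
    raise RuntimeError(
        f"could not build a valid {n_folds}-fold stratified partition "
        f"for class sizes {int(ypos.sum())}/{int((~ypos).sum())}"
    )


def _predict_scores(Xs: np.ndarray, comp: dict) -> np.ndarray:
    Xd = Xs.copy()
    for w_o, p_o in zip(comp["w_orth"], comp["p_orth"]):
        Xd -= np.outer(Xd @ w_o, p_o)
    return comp["b"] * (Xd @ comp["w"])


def _choose_n_orth(Xn_tr, ytr, cfg, rng) -> int:
    """Pick the orthogonal-component count by internal CV accuracy.

    Internal scaling statistics come from each internal training split;
    accuracy is pooled over internal folds; ties go to the smaller count.
    """
    ifolds = _draw_partition(ytr, cfg.internal_folds, rng)
    correct = np.zeros(cfg.max_orth + 1)
    totals = np.zeros(cfg.max_orth + 1)
    for g in range(cfg.internal_folds):
        te = ifolds == g
        tr = ~te
        if not te.any():
            continue
        mu, sc = pareto_stats(Xn_tr[tr])
        Xi = apply_pareto(Xn_tr[tr], mu, sc)
        yi = ytr[tr]
        yc = np.where(yi, 1.0, -1.0)
        yc = yc - yc.mean()
        path = opls_path(Xi, yc, cfg.max_orth)
        Xt = apply_pareto(Xn_tr[te], mu, sc)
        for k, comp in enumerate(path):
            s_tr = comp["b"] * comp["t"]
            thr = 0.5 * (s_tr[yi].mean() + s_tr[~yi].mean())
            pred = _predict_scores(Xt, comp) >= thr
            correct[k] += np.count_nonzero(pred == ytr[te])
            totals[k] += te.sum()
    acc = np.full(cfg.max_orth + 1, -1.0)
    ok = totals > 0
    acc[ok] = correct[ok] / totals[ok]
    return int(np.argmax(acc))  # ties resolve to the smallest count


def _cv_arm(
    Xn: np.ndarray,
    ypos: np.ndarray,
    cfg: CvConfig,
    seed_key: tuple,
    permute: bool,
    class_labels: tuple[str, str],
    keep_models: bool,
) -> CvResult:
    """Run one full arm of the scheme on the normalized matrix ``Xn``."""
    n, J = Xn.shape
    streams = np.random.SeedSequence(list(seed_key)).spawn(cfg.repetitions)
    rows = []
    vip_sum = np.zeros(J)
    models: list[OplsModel] = []
    for rep in range(cfg.repetitions):
        rng = np.random.default_rng(streams[rep])
        y_rep = rng.permutation(ypos) if permute else ypos
        fold = _draw_partition(y_rep, cfg.external_folds, rng)
        for f in range(cfg.external_folds):
            te = fold == f
            tr = ~te
            mu, sc = pareto_stats(Xn[tr])
            Xtr = apply_pareto(Xn[tr], mu, sc)
            ytr = y_rep[tr]
            n_orth = _choose_n_orth(Xn[tr], ytr, cfg, rng)
            yc = np.where(ytr, 1.0, -1.0)
            yc = yc - yc.mean()
            path = opls_path(Xtr, yc, n_orth)
            comp = path[min(n_orth, len(path) - 1)]
            n_orth_used = len(comp["w_orth"])
            s_tr = comp["b"] * comp["t"]
            thr = 0.5 * (s_tr[ytr].mean() + s_tr[~ytr].mean())
            Xte = apply_pareto(Xn[te], mu, sc)
            pred = _predict_scores(Xte, comp) >= thr
            yte = y_rep[te]
            correct = pred == yte
            acc = float(correct.mean())
            n_pos = int(yte.sum())
            n_neg = int(yte.size - n_pos)
            sens = float(correct[yte].mean()) if n_pos else np.nan
            spec = float(correct[~yte].mean()) if n_neg else np.nan
            vip_sum += np.sqrt(J) * np.abs(comp["w"])
            rows.append(
                {
                    "repetition": rep,
                    "fold": f,
                    "n_orth": n_orth_used,
                    "n_test": int(yte.size),
                    "accuracy": acc,
                    "sensitivity": sens,
                    "specificity": spec,
                }
            )
            if keep_models:
                models.append(
                    OplsModel(
                        w_pred=comp["w"],
                        p_pred=comp["p"],
                        b=comp["b"],
                        w_orth=comp["w_orth"],
                        p_orth=comp["p_orth"],
                        n_orth=n_orth_used,
                        class_labels=class_labels,
                        decision_threshold=float(thr),
                        train_column_means=mu,
                        train_column_scale=sc,
                    )
                )
    records = pd.DataFrame(rows)
    return CvResult(
        records=records,
        accuracies=records["accuracy"].to_numpy(),
        vip_mean=vip_sum / len(rows),
        models=models,
    )


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, BinMatrix):
        if X.state != "normalized":
            raise ValueError(
                f"cross-validation expects a normalized BinMatrix, got state={X.state!r}"
            )
        return X.values
    return np.asarray(X, dtype=float)


def _as_ypos(y, class_labels):
    y = np.asarray(y)
    uniq = list(dict.fromkeys(y.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    if class_labels is None:
        class_labels = (str(uniq[0]), str(uniq[1]))
    return y.astype(str) == class_labels[0], class_labels


def repeated_external_cv(
    X,
    y,
    cfg: CvConfig,
    class_labels: tuple[str, str] | None = None,
    keep_models: bool = True,
) -> CvResult:
    """True arm: stratified external folds × repetitions, no leakage.

    ``X`` is a normalized BinMatrix (or plain matrix of normalized bin
    integrals); scaling and hyperparameter choice happen inside each
    training split.  Returns per-model records, the accuracy vector, the
    per-bin mean VIP over all models and (optionally) the fitted models.
    The positive class for sensitivity is ``class_labels[0]``.
    """
    Xn = _as_matrix(X)
    ypos, class_labels = _as_ypos(y, class_labels)
    return _cv_arm(Xn, ypos, cfg, (cfg.seed, 0), False, class_labels, keep_models)


def permutation_null(
    X,
    y,
    cfg: CvConfig,
    class_labels: tuple[str, str] | None = None,
) -> np.ndarray:
    """Permutation arm: identical scheme, labels shuffled once per repetition.

    Returns the held-out accuracies of all external_folds × repetitions
    permuted models.
    """
    return permutation_null_result(X, y, cfg, class_labels).accuracies


def permutation_null_result(
    X,
    y,
    cfg: CvConfig,
    class_labels: tuple[str, str] | None = None,
) -> CvResult:
    """Like :func:`permutation_null` but returning the full per-model records."""
    Xn = _as_matrix(X)
    ypos, class_labels = _as_ypos(y, class_labels)
    return _cv_arm(Xn, ypos, cfg, (cfg.seed, 1), True, class_labels, False)


def ks_significance(
    true_acc,
    perm_acc,
    alpha: float = 0.001,
    method: str = "asymp",
) -> tuple[float, float, bool]:
    """One-sided two-sample KS: are true accuracies stochastically greater?

    D = sup over thresholds of (ECDF_perm − ECDF_true); the p-value uses the
    asymptotic Smirnov formula by default (``method='exact'`` for small
    samples).  Returns ``(D, p, p < alpha)``.
    """
    true_acc = np.asarray(true_acc, dtype=float)
    perm_acc = np.asarray(perm_acc, dtype=float)
    if true_acc.size == 0 or perm_acc.size == 0:
        raise ValueError("both accuracy arrays must be nonempty")
    res = sps.ks_2samp(perm_acc, true_acc, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def run_all_pairwise(
    matrix,
    design: pd.DataFrame,
    cfg: CvConfig,
    comparisons: tuple[tuple[str, str], ...] = COMPARISONS,
    alpha: float = 0.001,
    keep_models: bool = False,
) -> dict[str, ValidationReport]:
    """All pairwise group comparisons with true + permuted arms and KS calls.

    ``design`` needs ``sample_id`` and ``group`` columns aligned with the
    matrix rows.  The first group of each pair is the positive class.  Each
    comparison and arm draws from its own deterministic substream of
    ``cfg.seed``.
    """
    Xn = _as_matrix(matrix)
    groups = design["group"].to_numpy()
    present = set(groups.tolist())
    needed = {g for pair in comparisons for g in pair}
    missing = needed - present
    if missing:
        raise ValueError(f"design is missing groups {sorted(missing)}")

    out: dict[str, ValidationReport] = {}
    for i, (ga, gb) in enumerate(comparisons):
        sel = np.isin(groups, (ga, gb))
        Xc = Xn[sel]
        yc = groups[sel]
        ypos, labels = _as_ypos(yc, (ga, gb))
        true = _cv_arm(Xc, ypos, cfg, (cfg.seed, 2 * i), False, labels, keep_models)
        perm = _cv_arm(Xc, ypos, cfg, (cfg.seed, 2 * i + 1), True, labels, False)
        D, p, sig = ks_significance(true.accuracies, perm.accuracies, alpha=alpha)
        out[f"{ga} vs {gb}"] = ValidationReport(
            comparison=f"{ga} vs {gb}",
            true=true,
            perm=perm,
            ks_statistic=D,
            ks_p=p,
            significant=sig,
        )
    return out
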