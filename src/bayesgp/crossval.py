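"""k-fold cross-validated genomic prediction accuracy.

Accuracy is the Pearson correlation between held-out estimated breeding
values (EBVs) and genomic estimated breeding values (GEBVs) predicted from
marker effects trained on the remaining folds.  The default protocol is ten
folds, with the whole random split redrawn ten times and the per-repeat
mean correlations averaged into one accuracy figure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .blup import compute_ebv, fit_mixed_model
from .io import (
    EBVTable,
    GenotypeMatrix,
    PhenotypeRecords,
    ValidationError,
    write_cv_report,
)
from .regression import (
    ChainConfig,
    HyperParams,
    default_chain_config,
    derive_hyperparameters,
    predict_gebv,
    run_chain,
)


class UndefinedAccuracyError(ValueError):
    """Correlation is undefined (a vector with zero variance)."""


@dataclass
class FoldAssignment:
    """A random partition of n samples into k nearly equal folds."""

    n: int
    k: int
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.n,):
            raise ValidationError("labels must have length n")
        sizes = np.bincount(self.labels, minlength=self.k)
        if len(sizes) != self.k or sizes.max() - sizes.min() > 1 or sizes.min() < 1:
            raise ValidationError("folds must partition samples with sizes differing by <= 1")

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)


def make_folds(n: int, k: int, seed=None) -> FoldAssignment:
    """Uniformly random partition; the first n mod k folds get the extra sample."""
    if not 2 <= k <= n:
        raise ValidationError(f"need 2 <= k <= n (got k={k}, n={n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    labels = np.empty(n, dtype=int)
    start = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        labels[perm[start:start + size]] = fold
        start += size
    return FoldAssignment(n, k, labels, seed if isinstance(seed, int) else None)


def pearson_accuracy(ebv: np.ndarray, gebv: np.ndarray) -> float:
    """Sample Pearson correlation between observed EBVs and predicted GEBVs."""
    x = np.asarray(ebv, dtype=float).ravel()
    y = np.asarray(gebv, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors with >= 3 entries")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedAccuracyError("a vector has zero variance")
    return float(xd @ yd / np.sqrt(sx * sy))


@dataclass
class CVResult:
    """Per-fold correlations, per-repeat means, and the overall accuracy."""

    trait_name: str
    method: str
    fold_correlations: list
    repeat_means: list
    accuracy: float
    k: int
    repeats: int
    n_folds_dropped: int = 0
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        for c in self.fold_correlations:
            if not -1.0 <= c <= 1.0:
                raise ValidationError(f"correlation {c} outside [-1, 1]")

    def plot(self, ax=None):
        """Box of per-fold correlations with the overall accuracy marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.boxplot([self.fold_correlations], tick_labels=[self.method])
        ax.axhline(self.accuracy, color="C1", ls="--", lw=1,
                   label=f"accuracy = {self.accuracy:.3f}")
        ax.set_ylabel("fold correlation (EBV vs GEBV)")
        ax.set_title(self.trait_name)
        ax.legend(frameon=False)
        return ax


def cross_validate(
    ebv: EBVTable,
    g: GenotypeMatrix,
    method: str,
    cfg: ChainConfig | None = None,
    hp: HyperParams | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    r2_partition: float = 0.5,
    redraw_folds: bool = True,
) -> CVResult:
    """Repeated k-fold cross-validation of one method on one trait.

    Each repeat draws a fresh random fold assignment (set
    ``redraw_folds=False`` to reuse the first split across repeats); for
    each fold a chain is trained on the other k-1 folds, with prior scales
    re-derived from the training response, and the held-out genotypes are
    scored by the correlation between their EBVs and GEBVs.  Folds whose
    correlation is undefined are dropped from the means with a warning.
    """
    cfg = cfg or default_chain_config()
    missing = set(ebv.values.index) - set(g.sample_ids)
    if missing:
        raise ValidationError(f"EBV genotypes not in panel: {sorted(missing)[:10]}")
    if g.has_missing:
        raise ValidationError("genotype matrix has missing calls; impute first")
    keep = [i for i, s in enumerate(g.sample_ids) if s in set(ebv.values.index)]
    sample_ids = [g.sample_ids[i] for i in keep]
    Z = g.dosages[keep].astype(float)
    y = ebv.values.loc[sample_ids].to_numpy()
    n = len(y)
    if n < 3 * k:
        raise ValidationError(f"need n >= 3k for meaningful folds (n={n}, k={k})")

    root = np.random.SeedSequence(seed)
    fold_children = root.spawn(repeats)
    chain_children = root.spawn(repeats * k)

    fold_correlations: list = []
    repeat_means: list = []
    n_dropped = 0
    first_assignment = None
    for rep in range(repeats):
        if redraw_folds or first_assignment is None:
            assignment = make_folds(n, k, np.random.default_rng(fold_children[rep]))
            first_assignment = assignment
        else:
            assignment = first_assignment
        rep_corrs = []
        for fold in range(k):
            test = assignment.fold_indices(fold)
            train = np.flatnonzero(assignment.labels != fold)
            y_tr, Z_tr = y[train], Z[train]
            hp_fold = hp
            if hp_fold is None:
                hp_fold = derive_hyperparameters(
                    y_tr, Z_tr - Z_tr.mean(axis=0),
                    r2_partition=r2_partition,
                    pi_init=0.0 if method.lower() == "bayesa" else 0.5,
                )
            rng = np.random.default_rng(chain_children[rep * k + fold])
            ps = run_chain(y_tr, Z_tr, method, cfg, hp_fold, rng=rng)
            gebv = predict_gebv(ps, Z[test])
            try:
                corr = pearson_accuracy(y[test], gebv)
            except UndefinedAccuracyError:
                warnings.warn(
                    f"repeat {rep}, fold {fold}: undefined correlation, fold dropped",
                    stacklevel=2,
                )
                n_dropped += 1
                continue
            rep_corrs.append(corr)
            fold_correlations.append(corr)
        if rep_corrs:
            repeat_means.append(float(np.mean(rep_corrs)))
    if not repeat_means:
        raise UndefinedAccuracyError("every fold had undefined accuracy")
    return CVResult(
        trait_name=ebv.trait_name,
        method=method,
        fold_correlations=fold_correlations,
        repeat_means=repeat_means,
        accuracy=float(np.mean(repeat_means)),
        k=k,
        repeats=repeats,
        n_folds_dropped=n_dropped,
        config={
            "k": k, "repeats": repeats, "seed": seed,
            "n_iter": cfg.n_iter, "burn_in": cfg.burn_in, "thin": cfg.thin,
        },
    )


def run_full_pipeline(
    phenotypes: PhenotypeRecords,
    g: GenotypeMatrix,
    traits: list,
    methods: list,
    cfg: ChainConfig | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    out_path=None,
) -> list:
    """EBV extraction then cross-validated prediction for trait x method.

    For each trait: fit the mixed model, compute EBVs, then cross-validate
    every requested method.  One root seed drives everything; per-trait and
    per-method streams are spawned deterministically so results are
    reproducible and independent.
    """
    from .io import impute_missing_mode

    g = impute_missing_mode(g)
    root = np.random.SeedSequence(seed)
    results = []
    for t_idx, trait in enumerate(traits):
        try:
            vc = fit_mixed_model(phenotypes, trait)
            ebv = compute_ebv(phenotypes, trait, vc)
        except Exception as exc:
            raise RuntimeError(f"trait {trait!r}: EBV stage failed: {exc}") from exc
        for m_idx, method in enumerate(methods):
            sub_seed = int(
                np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(t_idx, m_idx)
                ).generate_state(1)[0] % (2**31)
            )
            try:
                res = cross_validate(ebv, g, method, cfg, k=k, repeats=repeats,
                                     seed=sub_seed)
            except Exception as exc:
                raise RuntimeError(
                    f"trait {trait!r}, method {method!r}: cross-validation failed: {exc}"
                ) from exc
            results.append(res)
    if out_path is not None:
        write_cv_report(results, out_path)
    return results


def plot_accuracies(results, ax=None):
    """Grouped bar chart of mean accuracy per trait and method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    traits = sorted({r.trait_name for r in results})
    methods = sorted({r.method for r in results})
    width = 0.8 / max(len(methods), 1)
    for mi, method in enumerate(methods):
        accs = [
            next((r.accuracy for r in results
                  if r.trait_name == t and r.method == method), np.nan)
            for t in traits
        ]
        xs = np.arange(len(traits)) + mi * width
        ax.bar(xs, accs, width=width, label=method)
    ax.set_xticks(np.arange(len(traits)) + 0.4 - width / 2)
    ax.set_xticklabels(traits, rotation=45, ha="right")
    ax.set_ylabel("prediction accuracy")
    ax.legend(frameon=False)
    return ax
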