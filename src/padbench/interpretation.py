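"""Activation-space analysis and explanatory linear models.

Two complementary views of how padding shapes what the models learn:

1. **Activation PCA** — for trained single-convolution models, the
   post-activation output of the convolutional layer for a small panel of
   test proteins is extracted per fold and per (non-augmented) padding
   mode.  Each of the 64 filters' length-``T`` activation rows is treated
   as a separate PCA sample; score densities stratified by padding mode
   and enzyme type describe how dense and sparse paddings structure the
   input space, and an OLS fit of PC1 on enzyme type + padding type
   quantifies the effect.

2. **Explanatory models** — ordinary least squares on per-label F1 with
   treatment-coded categorical factors (architecture, enzyme type,
   padding type), optionally with an interaction, answering the benchmark
   questions:

   * full: ``F1 ~ architecture + enzyme_type + type_padding`` over all
     cells (refs: only_denses, post; enzyme ref 0 for task 1, 1 for task 2);
   * A: padding effects for the baseline architecture (only_denses, all
     eight paddings, ref post);
   * B: switching between dense paddings (all architectures, ref
     stack_conv, paddings post/pre/mid/ext, padding:architecture
     interaction);
   * C: dense-to-sparse switch (as B with paddings post/strf/rnd/zoom);
   * D: is the padding-augmentation ensemble beneficial (paddings
     aug/post/strf, refs aug and stack_conv, interaction as B);
   * E: does the padding effect depend on the enzyme type (task 2 only,
     paddings post/strf, padding:enzyme_type interaction).

   Coefficient p-values are Benjamini-Hochberg adjusted within each
   fitted model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sp_stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .benchmark import ARCHITECTURES
from .data import LabeledSample, task_label
from .nn import Network
from .padding import SINGLE_MODES, PaddingConfig, pad

ALL_PADDINGS = ("post", "pre", "mid", "ext", "strf", "rnd", "zoom", "aug")


class InterpretationError(ValueError):
    pass


@dataclass
class ActivationMatrix:
    """First-conv activations (filters x T) for one prediction."""

    values: np.ndarray
    fold: int
    padding: str
    enzyme_type: str
    source_id: str


@dataclass
class PCAResult:
    loadings: np.ndarray              # components x T, orthonormal rows
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame              # pc1..pck + padding, enzyme_type, fold, ...


@dataclass
class LinearModelResult:
    question: str
    formula: str
    reference_levels: dict[str, str]
    intercept: float
    params: pd.DataFrame              # term, level, estimate, se, p, p_adj
    n_obs: int


def sample_test_proteins(test_samples: list[LabeledSample], task: int,
                         per_class: int | None = None, seed: int = 0) -> list[str]:
    """Randomly pick a per-class panel of test proteins.

    Defaults follow the activation study: 7 per class for task 1 (enzyme /
    non-enzyme) and 2 per class for task 2 (classes 1-7) — 14 ids either way.
    """
    if task == 1:
        classes, per_class = [0, 1], 7 if per_class is None else per_class
    elif task == 2:
        classes, per_class = list(range(1, 8)), 2 if per_class is None else per_class
    else:
        raise InterpretationError(f"task must be 1 or 2, got {task}")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for cls in classes:
        pool = sorted(s.id for s in test_samples
                      if (s.task1_label if task == 1 else (s.task2_label or 0)) == cls)
        if len(pool) < per_class:
            raise InterpretationError(
                f"class {cls} has only {len(pool)} test samples, need {per_class}")
        chosen.extend(rng.choice(pool, size=per_class, replace=False).tolist())
    return chosen


def extract_activations(models: dict[tuple[int, str], Network],
                        samples: dict[str, LabeledSample], ids: list[str],
                        task: int, T: int, alphabet, seed: int = 0,
                        modes=SINGLE_MODES) -> list[ActivationMatrix]:
    """One activation matrix per (fold x padding mode x protein).

    ``models`` maps ``(fold, mode)`` to a trained conv network; the
    augmentation mode is excluded by construction of ``modes``.
    """
    from .benchmark import encode_batch

    out: list[ActivationMatrix] = []
    for (fold, mode) in sorted(models):
        if mode not in modes:
            continue
        cfg = PaddingConfig(T=T, mode=mode, seed=seed)
        strings = [pad(samples[i].residues, cfg,
                       source_id=samples[i].origin_id or samples[i].id).symbols
                   for i in ids]
        X = encode_batch(strings, alphabet)
        acts = models[(fold, mode)].first_conv_activations(X)
        for k, sid in enumerate(ids):
            etype = str(task_label(samples[sid], task))
            out.append(ActivationMatrix(acts[k], fold, mode, etype, sid))
    return out


def pca_filters(matrices: list[ActivationMatrix], n_components: int = 10,
                seed: int = 0) -> PCAResult:
    """PCA with each filter's length-``T`` activation row as one sample.

    Stacking ``M`` matrices of ``F`` filters gives ``M x F`` samples of
    dimension ``T``.  Features are centred on the grand mean, not scaled.
    """
    if len(matrices) < 2:
        raise InterpretationError("need at least 2 activation matrices")
    X = np.vstack([m.values for m in matrices]).astype(np.float64)
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(X)
    F = matrices[0].values.shape[0]
    meta = pd.DataFrame({
        "padding": np.repeat([m.padding for m in matrices], F),
        "enzyme_type": np.repeat([m.enzyme_type for m in matrices], F),
        "fold": np.repeat([m.fold for m in matrices], F),
        "source_id": np.repeat([m.source_id for m in matrices], F),
        "filter": np.tile(np.arange(F), len(matrices)),
    })
    for k in range(n_components):
        meta[f"pc{k+1}"] = scores[:, k]
    return PCAResult(pca.components_, pca.explained_variance_ratio_, meta)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


_TERM_RE = re.compile(r"C\((?P<col>\w+),\s*Treatment\([^)]*\)\)\[T\.(?P<level>[^\]]+)\]")


def _tidy_params(fit) -> tuple[float, pd.DataFrame]:
    rows = []
    intercept = float(fit.params.get("Intercept", np.nan))
    for name in fit.params.index:
        if name == "Intercept":
            continue
        matches = _TERM_RE.findall(name)
        if matches:
            term = ":".join(col for col, _ in matches)
            level = ":".join(lev for _, lev in matches)
        else:
            term, level = name, ""
        rows.append(dict(term=term, level=level, estimate=float(fit.params[name]),
                         se=float(fit.bse[name]), p=float(fit.pvalues[name])))
    params = pd.DataFrame(rows)
    if len(params):
        params["p_adj"] = _bh_adjust(params["p"].to_numpy())
    else:
        params["p_adj"] = []
    return intercept, params


def fit_f1_model(table: pd.DataFrame, pad_ref: str, enzyme_ref: str,
                 arch_ref: str | None = None, interaction: str | None = None,
                 question: str = "custom") -> LinearModelResult:
    """OLS of per-label F1 on treatment-coded factors, BH-adjusted.

    ``table`` needs columns ``architecture, padding, enzyme_type, f1``.
    ``arch_ref=None`` drops the architecture term (single-architecture
    designs); ``interaction`` is ``None``, ``"padding:architecture"`` or
    ``"padding:enzyme_type"``.
    """
    table = table.copy()
    table["enzyme_type"] = table["enzyme_type"].astype(str)
    pad_term = f"C(padding, Treatment('{pad_ref}'))"
    enz_term = f"C(enzyme_type, Treatment('{enzyme_ref}'))"
    terms = []
    refs = {"padding": pad_ref, "enzyme_type": enzyme_ref}
    if arch_ref is not None:
        arch_term = f"C(architecture, Treatment('{arch_ref}'))"
        terms.append(arch_term)
        refs["architecture"] = arch_ref
    if table["enzyme_type"].nunique() > 1:
        terms.append(enz_term)
    terms.append(pad_term)
    if interaction == "padding:architecture":
        if arch_ref is None:
            raise InterpretationError(
                "padding:architecture interaction needs an architecture reference")
        terms.append(f"{pad_term}:{arch_term}")
    elif interaction == "padding:enzyme_type":
        terms.append(f"{pad_term}:{enz_term}")
    elif interaction is not None:
        raise InterpretationError(f"unknown interaction {interaction!r}")
    formula = "f1 ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=table).fit()
    intercept, params = _tidy_params(fit)
    return LinearModelResult(question, formula, refs, intercept, params, int(fit.nobs))


#: Architecture/padding subsets and reference levels per benchmark question.
QUESTION_DESIGNS = {
    "full": dict(archs=ARCHITECTURES, paddings=ALL_PADDINGS,
                 arch_ref="only_denses", pad_ref="post", interaction=None),
    "A": dict(archs=("only_denses",), paddings=ALL_PADDINGS,
              arch_ref=None, pad_ref="post", interaction=None),
    "B": dict(archs=ARCHITECTURES, paddings=("post", "pre", "mid", "ext"),
              arch_ref="stack_conv", pad_ref="post",
              interaction="padding:architecture"),
    "C": dict(archs=ARCHITECTURES, paddings=("post", "strf", "rnd", "zoom"),
              arch_ref="stack_conv", pad_ref="post",
              interaction="padding:architecture"),
    "D": dict(archs=ARCHITECTURES, paddings=("aug", "post", "strf"),
              arch_ref="stack_conv", pad_ref="aug",
              interaction="padding:architecture"),
    "E": dict(archs=ARCHITECTURES, paddings=("post", "strf"),
              arch_ref="stack_conv", pad_ref="post",
              interaction="padding:enzyme_type"),
}


def explain_f1(metrics_table: pd.DataFrame, question: str, task: int) -> LinearModelResult:
    """Fit the explanatory model for one benchmark question.

    The input is the long metrics table; response rows are the per-label F1
    values for ``task``.  The enzyme-type reference is 0 (non-enzyme) for
    task 1 and class 1 for task 2.
    """
    if question not in QUESTION_DESIGNS:
        raise InterpretationError(
            f"question must be one of {sorted(QUESTION_DESIGNS)}, got {question!r}")
    if question == "E" and task != 2:
        raise InterpretationError("question E is only applied to task 2")
    design = QUESTION_DESIGNS[question]
    df = metrics_table.query(
        "task == @task and metric == 'f1' and label != 'macro'").copy()
    df = df.rename(columns={"label": "enzyme_type", "value": "f1"})
    df = df[df["architecture"].isin(design["archs"])
            & df["padding"].isin(design["paddings"])]
    missing_a = set(design["archs"]) - set(df["architecture"])
    missing_p = set(design["paddings"]) - set(df["padding"])
    if missing_a or missing_p:
        raise InterpretationError(
            f"metrics table missing required architectures {sorted(missing_a)} "
            f"or paddings {sorted(missing_p)} for question {question}")
    enzyme_ref = "0" if task == 1 else "1"
    return fit_f1_model(df, pad_ref=design["pad_ref"], enzyme_ref=enzyme_ref,
                        arch_ref=design["arch_ref"],
                        interaction=design["interaction"], question=question)


def pc1_model(scores: pd.DataFrame, enzyme_ref: str = "1",
              pad_ref: str = "post") -> LinearModelResult:
    """OLS of PC1 on enzyme type + padding type (treatment-coded)."""
    df = scores.copy()
    df["enzyme_type"] = df["enzyme_type"].astype(str)
    formula = (f"pc1 ~ C(enzyme_type, Treatment('{enzyme_ref}')) "
               f"+ C(padding, Treatment('{pad_ref}'))")
    fit = smf.ols(formula, data=df).fit()
    refs = {"enzyme_type": enzyme_ref, "padding": pad_ref}
    intercept, params = _tidy_params(fit)
    return LinearModelResult("pc1", formula, refs, intercept, params, int(fit.nobs))


def score_density_grids(scores: pd.DataFrame, gridsize: int = 32,
                        by=("padding", "enzyme_type")) -> pd.DataFrame:
    """2-D kernel density of (PC1, PC2) per stratum, on a common grid."""
    x, y = scores["pc1"].to_numpy(), scores["pc2"].to_numpy()
    xg = np.linspace(x.min(), x.max(), gridsize)
    yg = np.linspace(y.min(), y.max(), gridsize)
    XX, YY = np.meshgrid(xg, yg)
    grid_pts = np.vstack([XX.ravel(), YY.ravel()])
    frames = []
    for keys, sub in scores.groupby(list(by)):
        if len(sub) < 4:
            continue
        try:
            kde = sp_stats.gaussian_kde(np.vstack([sub["pc1"], sub["pc2"]]))
            dens = kde(grid_pts)
        except np.linalg.LinAlgError:
            continue
        frame = pd.DataFrame({"pc1": grid_pts[0], "pc2": grid_pts[1],
                              "density": dens})
        for name, val in zip(by, keys if isinstance(keys, tuple) else (keys,)):
            frame[name] = val
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
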