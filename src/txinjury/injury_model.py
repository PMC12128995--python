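"""The injury-space model: correlation-PCA + 5-archetype archetypal analysis.

``InjuryModel`` is built from a :class:`~txinjury.scoring.ScoreTable` (the 10
standardized injury inputs); ``fit()`` returns an :class:`InjuryModelResults`
carrying PC loadings/scores/variance fractions with a deterministic
orientation, the fitted archetypes with per-biopsy archetype scores, injury
group labels (normal, AKI1, AKI2, mildCKD, CKDAKI), supplementary-variable
projection onto the factor map, per-PC top gene correlates, and an optional
2-D neighbour-graph embedding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .archetypes import ArchetypeModel, archetype_scores, fit_archetypes
from .io import ExpressionMatrix
from .scoring import (
    AKI_CONTRAST_COLUMNS,
    CKD_CONTRAST_COLUMNS,
    ScoreTable,
    standardize,
)

GROUP_LABELS = ["normal", "AKI1", "AKI2", "mildCKD", "CKDAKI"]


@dataclass
class PCAModel:
    """Correlation-PCA of the standardized score table.

    ``loadings`` is p x k orthonormal (columns PC1..PCk); ``scores`` is the
    n x k projection of the standardized inputs; variance fractions are the
    eigenvalues over the total variance p. ``orientation`` records, per PC,
    whether its sign was flipped and by which rule.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    scores: pd.DataFrame
    orientation: list[dict] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, standardized: pd.DataFrame) -> pd.DataFrame:
        """PC scores for new standardized rows (training convention)."""
        block = standardized[self.loadings.index]
        return pd.DataFrame(
            block.to_numpy() @ self.loadings.to_numpy(),
            index=standardized.index,
            columns=self.loadings.columns,
        )


def fit_pca(table: ScoreTable) -> PCAModel:
    """Eigendecomposition of the correlation matrix of the model inputs.

    The table must be standardized; requires n > p. Rank deficiency only
    warns (trailing zero eigenvalues are kept). A deterministic sign
    convention (largest-magnitude loading positive) is applied; the
    interpretation-level orientation of PC1-PC3 is done by
    :func:`orient_pcs`.
    """
    if not table.is_standardized:
        raise ValueError("fit_pca expects a standardized score table")
    X = table.inputs()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples than inputs (n={n}, p={p})")
    Z = X.to_numpy()
    # SVD of the standardized data; eigenvalues of the correlation matrix
    # are the squared singular values over n-1
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    if np.min(eig) < 1e-10 * np.max(eig):
        warnings.warn("rank-deficient input: some eigenvalues are ~0")
    V = Vt.T
    # sign convention: the largest-|loading| entry of each PC is positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    cols = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(V, index=X.columns, columns=cols)
    scores = pd.DataFrame(Z @ V, index=X.index, columns=cols)
    return PCAModel(
        loadings=loadings,
        eigenvalues=eig,
        variance_fractions=eig / eig.sum(),
        scores=scores,
    )


def orient_pcs(pca: PCAModel, table: ScoreTable) -> PCAModel:
    """Fix the signs of PC1-PC3 to the model's interpretation.

    PC1 points toward globally increased injury (positive correlation with
    the mean of the input scores); PC2 toward chronic injury (positive
    correlation with the CKD-minus-AKI score contrast); PC3 toward the
    low-function/remodeling pole (positive loading of lowGFR_Prob). A flip
    with an exactly-zero statistic keeps the sign and warns. Idempotent.
    """
    X = table.inputs()
    rules: list[tuple[str, pd.Series | None]] = []
    rules.append(("PC1", X.mean(axis=1)))
    aki = [c for c in AKI_CONTRAST_COLUMNS if c in X.columns]
    ckd = [c for c in CKD_CONTRAST_COLUMNS if c in X.columns]
    rules.append(("PC2", X[ckd].mean(axis=1) - X[aki].mean(axis=1) if aki and ckd else None))
    rules.append(("PC3", None))  # handled via the lowGFR loading below

    orientation = []
    for pc, stat in rules:
        if pc not in pca.scores.columns:
            continue
        if pc == "PC3":
            if "lowGFR_Prob" not in pca.loadings.index:
                continue
            value = float(pca.loadings.loc["lowGFR_Prob", pc])
            rule = "lowGFR_Prob loads positively"
        else:
            value = float(np.corrcoef(stat, pca.scores[pc])[0, 1])
            rule = (
                "mean input score correlates positively"
                if pc == "PC1"
                else "CKD-minus-AKI contrast correlates positively"
            )
        if value == 0:
            warnings.warn(f"{pc}: orientation statistic is exactly zero; sign kept")
            flipped = False
        else:
            flipped = value < 0
        if flipped:
            pca.loadings[pc] *= -1
            pca.scores[pc] *= -1
        orientation.append({"pc": pc, "rule": rule, "statistic": value, "flipped": flipped})
    pca.orientation = orientation
    return pca


def assign_group(
    alpha: np.ndarray | pd.DataFrame, labels: dict[int, str] | None = None
) -> np.ndarray:
    """Group label per biopsy: the archetype with the highest score.

    Ties break toward the lowest archetype index, deterministically.
    """
    A = np.asarray(getattr(alpha, "to_numpy", lambda: alpha)(), dtype=float)
    A = np.atleast_2d(A)
    if not np.isfinite(A).all():
        raise ValueError("non-finite archetype scores")
    idx = np.argmax(A, axis=1)  # argmax returns the first (lowest) index on ties
    if labels is None:
        return idx
    return np.array([labels[i] for i in idx])


def archetype_centroids(arch: ArchetypeModel, table: ScoreTable) -> pd.DataFrame:
    """Archetype positions expressed in standardized input-score space.

    When the archetypes were fitted in another space (e.g. PC scores), each
    archetype is still a convex combination of biopsies (rows of ``beta``),
    so its input-space position is that combination of the input scores.
    """
    inputs = table.inputs()
    if arch.column_names == list(inputs.columns):
        return pd.DataFrame(arch.archetypes, columns=inputs.columns)
    return pd.DataFrame(arch.beta @ inputs.to_numpy(), columns=inputs.columns)


def label_archetypes(
    arch: ArchetypeModel, table: ScoreTable, pca: PCAModel
) -> dict[int, str]:
    """Deterministic naming of the 5 archetypes from their injury features.

    In standardized input-score space: the archetype with the lowest mean
    input score is *normal*; of the rest, the two with the highest AKI-minus-
    CKD score contrast are the acute pair, split by PC1 position (*AKI2*
    higher, *AKI1* lower); of the remaining two, the one with higher mean
    acute-set scores is *CKDAKI*, the other *mildCKD*.
    """
    if arch.k != 5:
        raise ValueError(f"archetype labeling is defined for k=5, got k={arch.k}")
    cent = archetype_centroids(arch, table)
    aki = [c for c in AKI_CONTRAST_COLUMNS if c in cent.columns]
    ckd = [c for c in CKD_CONTRAST_COLUMNS if c in cent.columns]
    if not aki or not ckd:
        raise ValueError("labeling needs the AKI- and CKD-contrast input columns")

    labels: dict[int, str] = {}
    remaining = list(range(5))
    normal = int(cent.mean(axis=1).idxmin())
    labels[normal] = "normal"
    remaining.remove(normal)

    contrast = cent[aki].mean(axis=1) - cent[ckd].mean(axis=1)
    acute = sorted(remaining, key=lambda i: (-contrast[i], i))[:2]
    pc1 = pca.loadings["PC1"]
    pc1_pos = {i: float(cent.loc[i, pc1.index] @ pc1) for i in acute}
    aki2 = max(acute, key=lambda i: (pc1_pos[i], -i))
    aki1 = next(i for i in acute if i != aki2)
    labels[aki2] = "AKI2"
    labels[aki1] = "AKI1"

    chronic = [i for i in remaining if i not in acute]
    aki_mean = cent[aki].mean(axis=1)
    ckdaki = max(chronic, key=lambda i: (aki_mean[i], -i))
    mild = next(i for i in chronic if i != ckdaki)
    labels[ckdaki] = "CKDAKI"
    labels[mild] = "mildCKD"

    if sorted(labels.values()) != sorted(GROUP_LABELS):
        raise ValueError(f"non-bijective archetype labeling: {labels} (centroids:\n{cent})")
    return labels


def project_supplementary(pca: PCAModel, values: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Factor-map coordinates of variables not used in the fit.

    The coordinate of a variable on PCj is its Pearson correlation with the
    PCj scores, so supplementary gene-set means and archetype scores can be
    drawn on the same correlation circle as the inputs.
    """
    df = values.to_frame() if isinstance(values, pd.Series) else values
    df = df.loc[pca.scores.index]
    out = np.empty((df.shape[1], pca.n_components))
    S = pca.scores.to_numpy()
    Sc = S - S.mean(axis=0)
    s_norm = np.linalg.norm(Sc, axis=0)
    for j, col in enumerate(df.columns):
        v = df[col].to_numpy(dtype=float)
        vc = v - v.mean()
        nv = np.linalg.norm(vc)
        if nv == 0:
            raise ValueError(f"constant variable {col!r} cannot be projected")
        out[j] = (vc @ Sc) / (nv * s_norm)
    return pd.DataFrame(out, index=df.columns, columns=pca.scores.columns)


def pc_gene_correlations(
    expr: ExpressionMatrix,
    pca: PCAModel,
    top_n: int = 200,
    pcs: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Top genes correlating with each PC (Spearman), both directions.

    For each requested PC, returns a frame with columns ``rho`` and
    ``direction`` holding the ``top_n`` most positive and ``top_n`` most
    negative probe sets (ties broken by probe id for determinism).
    """
    pcs = pcs or ["PC1", "PC2", "PC3"]
    samples = [s for s in pca.scores.index if s in set(expr.sample_ids)]
    if len(samples) < 3:
        raise ValueError("need at least 3 overlapping biopsies")
    block = expr.values[samples].to_numpy()
    ranks = np.apply_along_axis(rankdata, 1, block)
    ranks -= ranks.mean(axis=1, keepdims=True)
    r_norm = np.linalg.norm(ranks, axis=1)
    r_norm[r_norm == 0] = np.inf  # constant probes get rho 0
    out: dict[str, pd.DataFrame] = {}
    for pc in pcs:
        sr = rankdata(pca.scores.loc[samples, pc].to_numpy())
        sr = sr - sr.mean()
        rho = (ranks @ sr) / (r_norm * np.linalg.norm(sr))
        tbl = pd.DataFrame({"rho": rho}, index=pd.Index(expr.probe_ids, name="probe_id"))
        pos = tbl.sort_values(["rho", "probe_id"], ascending=[False, True]).head(top_n)
        neg = tbl.sort_values(["rho", "probe_id"], ascending=[True, True]).head(top_n)
        pos = pos.assign(direction="positive")
        neg = neg.assign(direction="negative")
        out[pc] = pd.concat([pos, neg])
    return out


def embed_2d(table: ScoreTable, seed: int = 0, n_neighbors: int = 15) -> pd.DataFrame:
    """Seed-deterministic 2-D UMAP embedding of the standardized inputs.

    Visualization only — never used for inference.
    """
    X = table.inputs()
    if len(X) < 10:
        raise ValueError("need at least 10 biopsies for a 2-D embedding")
    import umap

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(X) - 1),
        random_state=seed,
    )
    coords = reducer.fit_transform(X.to_numpy())
    return pd.DataFrame(coords, index=X.index, columns=["UMAP1", "UMAP2"])


# ---------------------------------------------------------------------------
# Model / Results


class InjuryModel:
    """Injury-space model over a biopsy score table.

    Parameters
    ----------
    table : ScoreTable
        The per-biopsy score table; standardized internally if it is not
        already (parameters stored for projecting new biopsies).
    """

    def __init__(self, table: ScoreTable):
        self.raw_table = table
        self.table = table if table.is_standardized else standardize(table)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, roles: dict[str, str] | None = None):
        return cls(ScoreTable(df.copy(), dict(roles or {})))

    def fit(
        self,
        k: int = 5,
        n_restarts: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        seed: int = 0,
        archetype_space: str = "pc",
        n_pcs: int = 3,
        whiten: bool = True,
    ) -> "InjuryModelResults":
        """Fit the PCA and the k-archetype model.

        ``archetype_space`` selects where the archetypes live: the retained
        PC scores (``"pc"``, default, ``n_pcs`` components) or the
        standardized 10-score matrix (``"scores"``). In PC space the
        components are variance-standardized by default (``whiten``) so the
        dominant component does not swamp the minor but meaningful ones in
        the least-squares objective.
        """
        pca = orient_pcs(fit_pca(self.table), self.table)
        if archetype_space == "scores":
            data = self.table.inputs()
            scale = None
        elif archetype_space == "pc":
            data = pca.scores.iloc[:, :n_pcs]
            scale = data.std(ddof=1) if whiten else pd.Series(1.0, index=data.columns)
            data = data / scale
        else:
            raise ValueError("archetype_space must be 'scores' or 'pc'")
        arch = fit_archetypes(
            data, k=k, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed
        )
        if k == 5:
            arch.labels = label_archetypes(arch, self.table, pca)
        return InjuryModelResults(self, pca, arch, archetype_space, scale)


class InjuryModelResults:
    """Fitted injury space: PC scores, archetype scores, group labels."""

    def __init__(
        self,
        model: InjuryModel,
        pca: PCAModel,
        archetype_model: ArchetypeModel,
        archetype_space: str,
        archetype_scale: pd.Series | None = None,
    ):
        self.model = model
        self.table = model.table
        self.pca = pca
        self.archetype_model = archetype_model
        self.archetype_space = archetype_space
        self.archetype_scale = archetype_scale
        names = (
            [archetype_model.labels[i] for i in range(archetype_model.k)]
            if archetype_model.labels
            else [f"A{i + 1}" for i in range(archetype_model.k)]
        )
        self.archetype_scores = pd.DataFrame(
            archetype_model.alpha, index=self.table.df.index, columns=names
        )
        self.groups = pd.Series(
            assign_group(archetype_model.alpha, archetype_model.labels),
            index=self.table.df.index,
            name="injury_group",
        )

    # -- convenience views --------------------------------------------------
    @property
    def pc_scores(self) -> pd.DataFrame:
        return self.pca.scores

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.pca.variance_fractions

    def biopsy_frame(self) -> pd.DataFrame:
        """PC scores + archetype scores + group, one row per biopsy."""
        return pd.concat(
            [self.pc_scores.iloc[:, :3], self.archetype_scores, self.groups], axis=1
        )

    # -- projection of new biopsies ----------------------------------------
    def project(self, new_scores: pd.DataFrame) -> pd.DataFrame:
        """Project new biopsies (raw score columns) into the fitted space."""
        z = self.table.transform(new_scores)
        pcs = self.pca.project(z)
        if self.archetype_space == "scores":
            arch_in = z[self.archetype_model.column_names].to_numpy()
        else:
            cols = self.archetype_model.column_names
            arch_in = (pcs[cols] / self.archetype_scale[cols]).to_numpy()
        alpha = archetype_scores(self.archetype_model, arch_in)
        alpha_df = pd.DataFrame(alpha, index=z.index, columns=self.archetype_scores.columns)
        groups = pd.Series(
            assign_group(alpha, self.archetype_model.labels),
            index=z.index,
            name="injury_group",
        )
        return pd.concat([pcs.iloc[:, :3], alpha_df, groups], axis=1)

    # -- analyses hanging off the results ----------------------------------
    def project_supplementary(self, values) -> pd.DataFrame:
        return project_supplementary(self.pca, values)

    def factor_map(self, supplementary: pd.DataFrame | None = None) -> pd.DataFrame:
        """Correlation-circle coordinates of inputs (+ archetype scores and
        any supplementary variables) on the retained PCs."""
        rows = [
            project_supplementary(self.pca, self.table.inputs()).assign(role="input"),
            project_supplementary(self.pca, self.archetype_scores).assign(
                role="supplementary-archetype"
            ),
        ]
        if supplementary is not None:
            rows.append(
                project_supplementary(self.pca, supplementary).assign(
                    role="supplementary-gene-set"
                )
            )
        return pd.concat(rows)

    def pc_gene_correlations(self, expr: ExpressionMatrix, top_n: int = 200, pcs=None):
        return pc_gene_correlations(expr, self.pca, top_n=top_n, pcs=pcs)

    def embed_2d(self, seed: int = 0, n_neighbors: int = 15) -> pd.DataFrame:
        return embed_2d(self.table, seed=seed, n_neighbors=n_neighbors)

    def plot_factor_map(self, supplementary=None, x: str = "PC1", y: str = "PC2", ax=None):
        from .plotting import plot_factor_map

        return plot_factor_map(self.factor_map(supplementary), x=x, y=y, ax=ax)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        vf = self.variance_fractions
        lines = ["Injury space model", "=" * 50]
        lines.append(f"biopsies: {len(self.table.df)}   inputs: {len(self.table.input_columns)}")
        lines.append("")
        lines.append("PC   eigenvalue   % variance   orientation")
        orient = {o["pc"]: o for o in self.pca.orientation}
        for j in range(min(5, self.pca.n_components)):
            pc = f"PC{j + 1}"
            o = orient.get(pc)
            note = (o["rule"] + (" [flipped]" if o["flipped"] else "")) if o else "-"
            lines.append(
                f"{pc:<4} {self.pca.eigenvalues[j]:>10.3f}   {100 * vf[j]:>8.1f}%   {note}"
            )
        lines.append("")
        k = self.archetype_model.k
        lines.append(
            f"archetypes: k={k}, RSS={self.archetype_model.rss:.4g}, "
            f"converged={self.archetype_model.converged}"
        )
        lines.append("group sizes: " + ", ".join(
            f"{g}={n}" for g, n in self.groups.value_counts().items()
        ))
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "input_columns": list(self.table.inputs().columns),
            "standardization": {
                "means": self.table.means.to_dict(),
                "sds": self.table.sds.to_dict(),
            },
            "loadings": self.pca.loadings.to_dict(),
            "eigenvalues": self.pca.eigenvalues.tolist(),
            "variance_fractions": self.pca.variance_fractions.tolist(),
            "orientation": self.pca.orientation,
            "archetypes": self.archetype_model.archetypes.tolist(),
            "archetype_columns": self.archetype_model.column_names,
            "archetype_space": self.archetype_space,
            "archetype_scale": (
                self.archetype_scale.to_dict() if self.archetype_scale is not None else None
            ),
            "labels": {str(k): v for k, v in (self.archetype_model.labels or {}).items()},
            "seed": self.archetype_model.seed,
            "rss": self.archetype_model.rss,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
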