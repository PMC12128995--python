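"""Gene-set (PBT) scores against a control baseline and the model score table.

A PBT score is the mean log2 fold-change of a biopsy over the per-gene control
mean, averaged across the probe sets in the gene set; since the matrix stores
log2 intensities this is a geometric-mean fold change (``2**score`` is the
fold change on the natural scale). The model's score table holds, per biopsy,
the six transplant-derived input set scores, the four classifier
probabilities, and the twelve failed-repair set means as supplementary
(non-input) columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import ExpressionMatrix, GeneSetCollection
from .simulate import INPUT_PBT_SETS, NEW_GENE_SETS, MKI67_PROBE

logger = logging.getLogger(__name__)

#: Column names of the four classifier probabilities, in canonical order.
CLASSIFIER_COLUMNS = ["lowGFR_Prob", "Prot_Prob", "ci_gt1_Prob", "ct_gt1_Prob"]

#: The ten model input columns (six PBT scores + four classifier scores).
INPUT_COLUMNS = INPUT_PBT_SETS + CLASSIFIER_COLUMNS

#: Input columns regarded as acute-injury-related vs chronic-injury-related;
#: used for PC orientation and archetype labeling contrasts.
AKI_CONTRAST_COLUMNS = ["IRRAT30", "IRITD3", "IRITD5", "DAMP"]
CKD_CONTRAST_COLUMNS = ["MCAT", "IGT", "ci_gt1_Prob", "ct_gt1_Prob"]


@dataclass
class ScoreTable:
    """Per-biopsy score matrix with column roles and standardization state.

    ``roles`` maps column -> ``"input"`` | ``"supplementary"`` |
    ``"single-gene"``. After :func:`standardize`, ``means``/``sds`` hold the
    training-column parameters so new samples can be projected consistently.
    """

    df: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    means: pd.Series | None = None
    sds: pd.Series | None = None

    def __post_init__(self) -> None:
        for col in self.df.columns:
            self.roles.setdefault(col, "input")
        if self.means is None:  # raw (unstandardized) scale only
            for col in CLASSIFIER_COLUMNS:
                if col in self.df.columns:
                    vals = self.df[col].dropna()
                    if ((vals < 0) | (vals > 1)).any():
                        raise ValueError(f"classifier column {col!r} outside [0, 1]")

    @property
    def input_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.roles[c] == "input"]

    @property
    def supplementary_columns(self) -> list[str]:
        return [c for c in self.df.columns if self.roles[c] != "input"]

    @property
    def is_standardized(self) -> bool:
        return self.means is not None

    def inputs(self) -> pd.DataFrame:
        """The input-column block, in canonical order when available."""
        cols = [c for c in INPUT_COLUMNS if c in self.df.columns]
        extra = [c for c in self.input_columns if c not in cols]
        return self.df[cols + extra]

    def transform(self, new_df: pd.DataFrame) -> pd.DataFrame:
        """Project new samples with the stored standardization parameters."""
        if not self.is_standardized:
            raise ValueError("table has no stored standardization parameters")
        cols = [c for c in new_df.columns if c in self.means.index]
        return (new_df[cols] - self.means[cols]) / self.sds[cols]


def pbt_score(
    expr: ExpressionMatrix,
    members: list[str],
    control_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    name: str | None = None,
    warn_small: bool = True,
) -> pd.Series:
    """Mean log2 fold-change of ``members`` over the control-group mean.

    score_s = mean_g (x_gs - mean_c x_gc) over set members g present in the
    matrix; members absent from the matrix are dropped with a logged count.
    """
    controls = control_ids if control_ids is not None else expr.control_ids
    if not controls:
        raise ValueError("no control samples designated")
    present = [m for m in members if m in expr.values.index]
    if not present:
        raise ValueError(f"gene set {name or '?'}: no members present in the matrix")
    dropped = len(members) - len(present)
    if dropped:
        logger.info("gene set %s: %d absent members dropped", name or "?", dropped)
    if len(present) < 2 and warn_small:
        warnings.warn(
            f"gene set {name or '?'} reduced to {len(present)} probe set(s); "
            "its score is a single-probe value"
        )
    block = expr.values.loc[present]
    centered = block.sub(block[controls].mean(axis=1), axis=0)
    cols = sample_ids if sample_ids is not None else expr.sample_ids
    out = centered[cols].mean(axis=0)
    out.name = name
    return out


def fold_change(score: pd.Series | float):
    """Natural-scale fold change corresponding to a log2 score."""
    return 2.0 ** score


def score_table(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    classifier_probs: pd.DataFrame,
    control_ids: list[str] | None = None,
    include_mki67: bool = True,
) -> ScoreTable:
    """Assemble the model score table: 10 inputs + supplementary set means.

    One row per non-control biopsy. Input columns are the six transplant PBT
    scores plus the four classifier probabilities; the twelve failed-repair
    set means (and optionally the MKI67 probe value) are tagged supplementary
    and excluded from model fitting.
    """
    controls = control_ids if control_ids is not None else expr.control_ids
    biopsies = [s for s in expr.sample_ids if s not in set(controls)]

    missing = [s for s in INPUT_PBT_SETS if s not in sets]
    missing += [c for c in CLASSIFIER_COLUMNS if c not in classifier_probs.columns]
    if missing:
        raise ValueError(f"missing model inputs: {missing}")

    cols: dict[str, pd.Series] = {}
    roles: dict[str, str] = {}
    for s in INPUT_PBT_SETS:
        cols[s] = pbt_score(expr, sets[s], controls, biopsies, name=s)
        roles[s] = "input"
    probs = classifier_probs.reindex(biopsies)
    for c in CLASSIFIER_COLUMNS:
        cols[c] = probs[c]
        roles[c] = "input"
    for s in NEW_GENE_SETS:
        if s in sets:
            cols[s] = pbt_score(expr, sets[s], controls, biopsies, name=s)
            roles[s] = "supplementary"
    if include_mki67 and MKI67_PROBE in expr.values.index:
        mki = pbt_score(
            expr, [MKI67_PROBE], controls, biopsies, name="MKI67", warn_small=False
        )
        cols["MKI67"] = mki
        roles["MKI67"] = "single-gene"

    df = pd.DataFrame(cols, index=pd.Index(biopsies, name="sample_id"))
    return ScoreTable(df, roles)


def standardize(table: ScoreTable, ddof: int = 1) -> ScoreTable:
    """Z-score every column, storing per-column mean/sd for later projection.

    The sd uses the n-1 denominator. A zero-variance column is an error since
    it cannot be standardized.
    """
    if len(table.df) < 2:
        raise ValueError("need at least 2 biopsies to standardize")
    means = table.df.mean()
    sds = table.df.std(ddof=ddof)
    zero = sds.index[(sds == 0) | sds.isna()].tolist()
    if zero:
        raise ValueError(f"zero-variance columns cannot be standardized: {zero}")
    z = (table.df - means) / sds
    return ScoreTable(z, dict(table.roles), means=means, sds=sds)


def pairwise_set_correlations(
    table: ScoreTable, columns: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix between score columns."""
    cols = columns if columns is not None else list(table.df.columns)
    if len(table.df) < 3:
        raise ValueError("need at least 3 biopsies for correlations")
    rho = spearmanr(table.df[cols].to_numpy()).statistic
    rho = np.atleast_2d(rho)
    if rho.shape != (len(cols), len(cols)):  # spearmanr collapses the 2-col case
        r = rho.item() if rho.size == 1 else rho[0, 1]
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cols, columns=cols)
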