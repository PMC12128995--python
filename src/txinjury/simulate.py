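"""Synthetic transplant-biopsy cohorts with known injury structure.

The generator emulates a biopsy population whose expression variance is driven
by three latent injury axes — acute injury/inflammation (z1), chronicity
coupled to time posttransplant (z2), and epithelial remodeling (z3) — with
five planted injury states (normal, AKI1, AKI2, mild CKD, CKDAKI) placed at
vertices in latent space. Donor age couples to the remodeling axis, eGFR
declines with the acute and remodeling axes, and graft failure hazard rises
with the acute axis (increasingly so for late biopsies) and the remodeling
axis. Everything downstream — gene-set scores, classifiers, the PCA/archetype
injury space and the survival models — can therefore be checked against
ground truth.

Every quantity that affects the output is a :class:`CohortConfig` field; the
generator is seed-deterministic and the config round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, SampleMetadata

#: The six transplant-derived input gene sets: four acute-injury-related
#: (AKI-like, loading on z1) and two chronic-injury-related (CKD-like, z2).
AKI_INPUT_SETS = ["IRRAT30", "IRITD3", "IRITD5", "DAMP"]
CKD_INPUT_SETS = ["MCAT", "IGT"]
INPUT_PBT_SETS = AKI_INPUT_SETS + CKD_INPUT_SETS

#: Twelve failed-repair epithelial-state signatures: four biological states
#: (New1 oxidative stress, New2 hypoxia, New3 interferon response, New4 EMT)
#: per nephron segment. The thick-ascending-limb New1 set is replaced by the
#: thin-limb set so each state is represented by 3 segments.
NEW_GENE_SETS = (
    ["PT_New1", "tL_New1", "DCT_New1"]
    + [f"{seg}_New{i}" for i in (2, 3, 4) for seg in ("PT", "TAL", "DCT")]
)

STATE_LABELS = ["normal", "AKI1", "AKI2", "mildCKD", "CKDAKI"]

MKI67_PROBE = "11721143_a_at"


def _default_set_sizes() -> dict[str, int]:
    sizes = {name: 30 for name in INPUT_PBT_SETS}
    sizes.update({name: 20 for name in NEW_GENE_SETS})
    return sizes


def _default_set_loadings() -> dict[str, list[float]]:
    """Per-set (z1, z2, z3) loadings, in log2 units per latent unit.

    Sign structure mirrors the biology the axes stand for: acute sets load on
    z1 with small opposite-sign z3 contrasts (remodeling varies *within* AKI),
    chronic sets load on z2 with opposite-sign z3 contrasts (mast-cell-like up,
    immunoglobulin-like down with remodeling); the failed-repair sets load on
    remodeling plus acute injury, with the oxidative-stress (New1) sets
    *anti*-correlated with acute injury and the EMT (New4) sets loading on it
    most strongly.
    """
    loadings: dict[str, list[float]] = {
        "IRRAT30": [1.0, 0.0, -0.2],
        "IRITD3": [1.0, 0.0, -0.2],
        "IRITD5": [1.0, 0.0, -0.3],
        "DAMP": [1.0, 0.0, -0.2],
        "MCAT": [0.0, 1.0, 0.3],
        "IGT": [0.0, 1.0, -0.3],
    }
    for seg in ("PT", "tL", "DCT"):
        loadings[f"{seg}_New1"] = [-0.6, 0.0, 0.4]
    for seg in ("PT", "TAL", "DCT"):
        loadings[f"{seg}_New2"] = [0.5, -0.3, 0.35]
        loadings[f"{seg}_New3"] = [0.5, -0.3, 0.35]
        loadings[f"{seg}_New4"] = [0.9, -0.3, 0.6]
    return loadings


def _default_state_vertices() -> dict[str, list[float]]:
    # (z1, z2, z3): AKI states early (negative z2), CKD states late; the
    # acute axis separates AKI2>AKI1 and CKDAKI>mildCKD; remodeling is high
    # in AKI1 and CKDAKI.
    return {
        "normal": [0.0, 0.0, 0.0],
        "AKI1": [1.5, -1.2, 1.5],
        "AKI2": [3.0, -1.2, 0.0],
        "mildCKD": [1.0, 1.5, 0.0],
        "CKDAKI": [2.5, 1.5, 1.5],
    }


@dataclass
class LatentParams:
    """Latent-state geometry and measurement noise.

    ``state_probs`` are the planted state frequencies; ``within_state_sd`` is
    the per-axis Gaussian scatter around each vertex (latent units);
    ``noise_sd`` is per-probe expression noise in log2 units.
    """

    state_vertices: dict[str, list[float]] = field(default_factory=_default_state_vertices)
    state_probs: dict[str, float] = field(
        default_factory=lambda: {
            "normal": 0.35, "AKI1": 0.10, "AKI2": 0.15, "mildCKD": 0.20, "CKDAKI": 0.20,
        }
    )
    within_state_sd: float = 0.4
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.2

    def validate(self) -> None:
        if self.noise_sd < 0 or self.within_state_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if set(self.state_vertices) != set(STATE_LABELS):
            raise ValueError(f"state vertices must be exactly {STATE_LABELS}")
        p = np.array([self.state_probs[s] for s in STATE_LABELS])
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("state probabilities must be a distribution")


@dataclass
class TimeModel:
    """Time from transplant to biopsy: log-uniform with a z2 coupling.

    TxBx is log-uniform on [min_days, max_days] marginally (via a Gaussian
    rank transform) and correlated with the chronicity axis z2 at
    ``z2_coupling`` — late biopsies carry more chronic injury.
    """

    min_days: float = 3.0
    max_days: float = 15 * 365.0
    z2_coupling: float = 0.85

    def validate(self) -> None:
        if not 0 < self.min_days < self.max_days:
            raise ValueError("need 0 < min_days < max_days")
        if not -1 <= self.z2_coupling <= 1:
            raise ValueError("z2_coupling must be in [-1, 1]")


@dataclass
class AgeModel:
    """Donor age (years), Gaussian, correlated with the remodeling axis."""

    mean: float = 45.0
    sd: float = 13.0
    z3_coupling: float = 0.2

    def validate(self) -> None:
        if self.sd <= 0:
            raise ValueError("age sd must be > 0")
        if not -1 <= self.z3_coupling <= 1:
            raise ValueError("z3_coupling must be in [-1, 1]")


@dataclass
class EgfrModel:
    """eGFR (mL/min/1.73m2): baseline plus per-axis slopes plus noise.

    Function falls with acute injury and remodeling; the positive z2 slope
    encodes that the lowest-function biopsies are the early acute ones.
    """

    baseline: float = 50.0
    slopes: list[float] = field(default_factory=lambda: [-6.0, 2.0, -4.0])
    noise_sd: float = 9.0
    floor: float = 5.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("egfr noise sd must be >= 0")
        if len(self.slopes) != 3:
            raise ValueError("need one eGFR slope per latent axis")


@dataclass
class HazardParams:
    """Death-censored graft-failure hazard (per day) and competing events.

    log-hazard = log(baseline) + (acute_coef + acute_time_slope *
    (log TxBx - log 365)) * z1 + chronic_coef * z2 + remodeling_coef * z3.
    The acute-axis effect grows linearly with log time-posttransplant
    (``acute_coef`` is its value at one year; the defaults put it near zero
    for first-weeks biopsies and strongest for late ones), while the
    remodeling-axis effect is constant at all times. Death with function is
    an independent exponential competing event; a ``censoring_rate`` fraction
    of kidneys get a uniform administrative censor before the horizon.
    """

    baseline: float = 8e-5
    acute_coef: float = 0.5
    acute_time_slope: float = 0.15
    chronic_coef: float = 0.0
    remodeling_coef: float = 0.35
    death_rate: float = 1.5e-5
    censoring_rate: float = 0.3
    horizon_days: float = 3650.0

    def validate(self) -> None:
        if self.baseline <= 0 or self.death_rate < 0:
            raise ValueError("hazard rates must be positive")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring rate must be in [0, 1]")


@dataclass
class CohortConfig:
    """Complete recipe for one synthetic cohort (seed-deterministic)."""

    n_biopsies: int = 1000
    n_controls: int = 4
    n_probesets: int = 2000
    seed: int = 0
    gene_set_sizes: dict[str, int] = field(default_factory=_default_set_sizes)
    set_loadings: dict[str, list[float]] = field(default_factory=_default_set_loadings)
    latent_params: LatentParams = field(default_factory=LatentParams)
    time_model: TimeModel = field(default_factory=TimeModel)
    age_model: AgeModel = field(default_factory=AgeModel)
    egfr_model: EgfrModel = field(default_factory=EgfrModel)
    hazard_params: HazardParams = field(default_factory=HazardParams)
    repeat_biopsy_rate: float = 0.15
    proteinuria_logit: list[float] = field(default_factory=lambda: [-1.2, 0.6, 0.6, 0.0])
    ci_loadings: list[float] = field(default_factory=lambda: [0.3, 1.2, 0.0])
    ct_loadings: list[float] = field(default_factory=lambda: [0.3, 1.2, 0.0])
    lesion_cutpoints: list[float] = field(default_factory=lambda: [0.8, 1.8, 2.8])
    lesion_noise_sd: float = 1.0
    cortex_range: list[float] = field(default_factory=lambda: [5.0, 95.0])
    mki67_loadings: list[float] = field(default_factory=lambda: [0.4, -0.4, 0.1])

    def validate(self) -> None:
        if min(self.n_biopsies, self.n_controls, self.n_probesets) <= 0:
            raise ValueError("all counts must be > 0")
        needed = sum(self.gene_set_sizes.values()) + 1  # +1 for the MKI67 probe
        if self.n_probesets < needed:
            raise ValueError(
                f"n_probesets={self.n_probesets} < {needed} probes required by gene sets"
            )
        for name in self.gene_set_sizes:
            if name not in self.set_loadings:
                raise ValueError(f"no loadings configured for gene set {name!r}")
            if self.gene_set_sizes[name] <= 0:
                raise ValueError(f"gene set {name!r} has non-positive size")
        if not 0 <= self.repeat_biopsy_rate < 1:
            raise ValueError("repeat_biopsy_rate must be in [0, 1)")
        self.latent_params.validate()
        self.time_model.validate()
        self.age_model.validate()
        self.egfr_model.validate()
        self.hazard_params.validate()

    # -- lossless JSON round-trip ------------------------------------------
    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CohortConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        for key, sub in (
            ("latent_params", LatentParams),
            ("time_model", TimeModel),
            ("age_model", AgeModel),
            ("egfr_model", EgfrModel),
            ("hazard_params", HazardParams),
        ):
            if isinstance(data.get(key), dict):
                data[key] = sub(**data[key])
        return cls(**data)


@dataclass
class CohortTruth:
    """Ground-truth latents, planted state labels, and hazard multipliers."""

    df: pd.DataFrame  # columns: z1, z2, z3, true_state_label, true_hazard

    def __post_init__(self) -> None:
        labels = set(self.df["true_state_label"].unique())
        if not labels <= set(STATE_LABELS):
            raise ValueError(f"unexpected state labels: {labels - set(STATE_LABELS)}")

    @property
    def latents(self) -> np.ndarray:
        return self.df[["z1", "z2", "z3"]].to_numpy()


# ---------------------------------------------------------------------------

def _probe_layout(config: CohortConfig):
    """Deterministic assignment of probes to gene sets (first probes, in
    fixed set order), the MKI67 probe, and background probes."""
    probes = [f"ps{i:05d}_at" for i in range(config.n_probesets - 1)] + [MKI67_PROBE]
    sets: dict[str, list[str]] = {}
    cursor = 0
    for name in list(INPUT_PBT_SETS) + list(NEW_GENE_SETS):
        if name not in config.gene_set_sizes:
            continue
        k = config.gene_set_sizes[name]
        sets[name] = probes[cursor : cursor + k]
        cursor += k
    for name in config.gene_set_sizes:  # any extra user-defined sets
        if name not in sets:
            k = config.gene_set_sizes[name]
            sets[name] = probes[cursor : cursor + k]
            cursor += k
    tags = {n: "input-PBT" for n in INPUT_PBT_SETS if n in sets}
    tags.update({n: "new-gene-set" for n in NEW_GENE_SETS if n in sets})
    return probes, GeneSetCollection(sets, tags)


def _loading_matrix(config: CohortConfig, probes, collection) -> np.ndarray:
    L = np.zeros((len(probes), 3))
    index = {p: i for i, p in enumerate(probes)}
    for name, members in collection.sets.items():
        lam = np.asarray(config.set_loadings[name], dtype=float)
        for p in members:
            L[index[p]] = lam
    L[index[MKI67_PROBE]] = np.asarray(config.mki67_loadings, dtype=float)
    return L


def _baseline(config: CohortConfig, n_probes: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 0])
    lp = config.latent_params
    return lp.baseline_mean + lp.baseline_sd * rng.standard_normal(n_probes)


def _corr_mix(rng, anchor: np.ndarray, coupling: float) -> np.ndarray:
    """Standard-normal variate correlated with standardized ``anchor``."""
    z = (anchor - anchor.mean()) / anchor.std()
    eps = rng.standard_normal(len(anchor))
    return coupling * z + np.sqrt(max(0.0, 1 - coupling**2)) * eps


def generate_controls(config: CohortConfig) -> ExpressionMatrix:
    """Control (nephrectomy-like) samples: baseline expression, latents at 0."""
    config.validate()
    probes, _ = _probe_layout(config)
    baseline = _baseline(config, len(probes))
    rng = np.random.default_rng([config.seed, 1])
    noise = config.latent_params.noise_sd * rng.standard_normal(
        (len(probes), config.n_controls)
    )
    ids = [f"CTRL{i + 1}" for i in range(config.n_controls)]
    df = pd.DataFrame(baseline[:, None] + noise, index=probes, columns=ids)
    return ExpressionMatrix(df, control_ids=ids)


def generate_cohort(config: CohortConfig):
    """Generate one cohort: expression (controls included), metadata, gene
    sets, and ground truth.

    Returns
    -------
    (ExpressionMatrix, SampleMetadata, GeneSetCollection, CohortTruth)
        The expression matrix contains the biopsies plus ``n_controls``
        control columns (flagged via ``control_ids``). Metadata covers the
        biopsies only.
    """
    config.validate()
    n = config.n_biopsies
    lp = config.latent_params
    probes, collection = _probe_layout(config)
    baseline = _baseline(config, len(probes))
    L = _loading_matrix(config, probes, collection)

    rng = np.random.default_rng([config.seed, 2])

    # -- latent states ------------------------------------------------------
    probs = np.array([lp.state_probs[s] for s in STATE_LABELS])
    state_idx = rng.choice(len(STATE_LABELS), size=n, p=probs)
    vertices = np.array([lp.state_vertices[s] for s in STATE_LABELS])
    z = vertices[state_idx] + lp.within_state_sd * rng.standard_normal((n, 3))

    # -- expression ---------------------------------------------------------
    signal = baseline[:, None] + L @ z.T
    expr = signal + lp.noise_sd * rng.standard_normal((len(probes), n))
    biopsy_ids = [f"BX{i + 1:05d}" for i in range(n)]
    controls = generate_controls(config)
    values = pd.concat(
        [pd.DataFrame(expr, index=probes, columns=biopsy_ids), controls.values], axis=1
    )
    expr_matrix = ExpressionMatrix(values, control_ids=controls.control_ids)

    # -- clinical metadata --------------------------------------------------
    tm = config.time_model
    w = _corr_mix(rng, z[:, 1], tm.z2_coupling)
    from scipy.stats import norm

    u = norm.cdf(w)
    txbx = np.exp(np.log(tm.min_days) + u * (np.log(tm.max_days) - np.log(tm.min_days)))

    am = config.age_model
    donor_age = np.clip(am.mean + am.sd * _corr_mix(rng, z[:, 2], am.z3_coupling), 12, 85)

    em = config.egfr_model
    egfr = (
        em.baseline
        + z @ np.asarray(em.slopes)
        + em.noise_sd * rng.standard_normal(n)
    )
    egfr = np.maximum(egfr, em.floor)

    b0, b1, b2, b3 = config.proteinuria_logit
    p_prot = 1.0 / (1.0 + np.exp(-(b0 + b1 * z[:, 0] + b2 * z[:, 1] + b3 * z[:, 2])))
    proteinuria = (rng.uniform(size=n) < p_prot).astype(int)

    def lesion(loads):
        latent = z @ np.asarray(loads) + config.lesion_noise_sd * rng.standard_normal(n)
        return np.digitize(latent, config.lesion_cutpoints)

    ci = lesion(config.ci_loadings)
    ct = lesion(config.ct_loadings)
    pct_cortex = rng.uniform(*config.cortex_range, size=n)

    # -- kidneys (repeat biopsies share a kidney id) ------------------------
    kidney_ids = []
    for i in range(n):
        if i > 0 and rng.uniform() < config.repeat_biopsy_rate:
            kidney_ids.append(kidney_ids[rng.integers(i)])
        else:
            kidney_ids.append(f"K{i + 1:05d}")

    # -- survival -----------------------------------------------------------
    hp = config.hazard_params
    log_time_centered = np.log(txbx) - np.log(365.0)
    log_mult = (
        (hp.acute_coef + hp.acute_time_slope * log_time_centered) * z[:, 0]
        + hp.chronic_coef * z[:, 1]
        + hp.remodeling_coef * z[:, 2]
    )
    true_hazard = np.exp(log_mult)
    t_fail = rng.exponential(1.0 / (hp.baseline * true_hazard))
    t_death = (
        rng.exponential(1.0 / hp.death_rate, size=n)
        if hp.death_rate > 0
        else np.full(n, np.inf)
    )
    admin = np.where(
        rng.uniform(size=n) < hp.censoring_rate,
        rng.uniform(1.0, hp.horizon_days, size=n),
        hp.horizon_days,
    )
    followup = np.minimum.reduce([t_fail, t_death, admin])
    followup = np.maximum(followup, 1.0)
    graft_failed = (t_fail <= np.minimum(t_death, admin)).astype(int)
    died = ((t_death < t_fail) & (t_death <= admin)).astype(int)

    rejection_group = np.where(rng.uniform(size=n) < 0.55, "no rejection", "rejection")

    meta = SampleMetadata(
        pd.DataFrame(
            {
                "kidney_id": kidney_ids,
                "txbx_days": txbx,
                "egfr": egfr,
                "donor_age": donor_age,
                "proteinuria_pos": proteinuria,
                "ci_score": ci,
                "ct_score": ct,
                "pct_cortex": pct_cortex,
                "rejection_group": rejection_group,
                "followup_days": followup,
                "graft_failed": graft_failed,
                "died_with_function": died,
            },
            index=pd.Index(biopsy_ids, name="sample_id"),
        )
    )

    truth = CohortTruth(
        pd.DataFrame(
            {
                "z1": z[:, 0],
                "z2": z[:, 1],
                "z3": z[:, 2],
                "true_state_label": [STATE_LABELS[i] for i in state_idx],
                "true_hazard": true_hazard,
            },
            index=pd.Index(biopsy_ids, name="sample_id"),
        )
    )
    return expr_matrix, meta, collection, truth
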