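"""Matplotlib views of the fitted injury space and survival curves."""

from __future__ import annotations

import numpy as np

_ROLE_STYLE = {
    "input": dict(color="tab:red", marker="o"),
    "supplementary-archetype": dict(color="tab:green", marker="^"),
    "supplementary-gene-set": dict(color="tab:blue", marker="s"),
}


def plot_factor_map(factor_map, x: str = "PC1", y: str = "PC2", ax=None):
    """Correlation circle: variables at their (corr with PCx, corr with PCy).

    ``factor_map`` is the frame returned by
    :meth:`InjuryModelResults.factor_map` (coordinates + a ``role`` column).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="0.8", lw=1)
    ax.axhline(0, color="0.9", lw=0.8)
    ax.axvline(0, color="0.9", lw=0.8)
    for role, style in _ROLE_STYLE.items():
        block = factor_map[factor_map["role"] == role]
        if not len(block):
            continue
        ax.scatter(block[x], block[y], label=role, s=30, **style)
        for name, row in block.iterrows():
            ax.annotate(str(name), (row[x], row[y]), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel(f"correlation with {x}")
    ax.set_ylabel(f"correlation with {y}")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.legend(fontsize=8, loc="lower right")
    return ax


def plot_km(curves: dict, ax=None, max_days: float = 3 * 365.0):
    """Step plot of per-group Kaplan-Meier curves from :func:`km_curve`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for group, curve in curves.items():
        ax.step(curve["timeline"], curve["survival"], where="post", label=str(group))
    ax.set_xlim(0, max_days)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("days after biopsy")
    ax.set_ylabel("death-censored graft survival")
    ax.legend(fontsize=8)
    return ax


def plot_time_varying_effect(effect, t_min: float = 3.0, t_max: float = 5475.0, ax=None):
    """beta(t) with its pointwise delta-method band, log-time axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = np.exp(np.linspace(np.log(t_min), np.log(t_max), 200))
    lo, hi = effect.band(t)
    ax.plot(t, effect.beta(t), color="tab:blue", label=effect.name)
    ax.fill_between(t, lo, hi, alpha=0.2, color="tab:blue")
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("days posttransplant at biopsy")
    ax.set_ylabel("log-hazard effect")
    ax.legend(fontsize=8)
    return ax
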