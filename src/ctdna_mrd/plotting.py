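"""Minimal plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

from .outcomes import SurvivalFit


def plot_km(fits: dict[str, SurvivalFit], ax=None, title: str | None = None):
    """Step-plot one Kaplan–Meier curve per labelled group."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, fit in fits.items():
        times = [0.0] + [p.time for p in fit.curve]
        surv = [1.0] + [p.survival for p in fit.curve]
        ax.step(times, surv, where="post", label=f"{label} (n={fit.n})")
    ax.set_xlabel("days since treatment completion")
    ax.set_ylabel("progression-free survival")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
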