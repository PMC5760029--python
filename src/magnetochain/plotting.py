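"""Small built-in figures for protocol outputs (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_rupture_traces(traces, path) -> None:
    """theta_m and bound count versus field angle, one line per seed."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for label, trace in traces:
        ax1.plot(trace["theta_b"], trace["theta_m_mean"], lw=0.9, label=str(label))
        ax2.plot(trace["theta_b"], trace["bound_mean"], lw=0.9)
    ax1.set_xlabel(r"field angle $\theta_B$ (deg)")
    ax1.set_ylabel(r"moment angle $\theta_m$ (deg)")
    ax2.set_xlabel(r"field angle $\theta_B$ (deg)")
    ax2.set_ylabel("bound particles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_census_fractions(fractions, path) -> None:
    """Stacked bar chart of structure-class fractions per binding energy."""
    ax = fractions.plot.bar(stacked=True, figsize=(6, 3.5))
    ax.set_xlabel(r"binding energy $|E_b|$ ($k_BT$)")
    ax.set_ylabel("fraction of configurations")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
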