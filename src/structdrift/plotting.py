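"""Minimal plotting helpers: the CE diagram and time-to-stasis scatter."""

from __future__ import annotations


def plot_ce_diagram(ce_points, ax=None, **scatter_kw):
    """Scatter h_mu (x) vs C_mu (y), colored by subspace signature.

    ``ce_points`` is the DataFrame from :func:`structdrift.subspaces.ce_diagram`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    for i, (sig, grp) in enumerate(ce_points.groupby("signature")):
        ax.scatter(grp["h_mu"], grp["C_mu"], s=8, label=f"subspace {i}", **scatter_kw)
    ax.set_xlabel(r"allelic entropy $h_\mu$ [bits/allele]")
    ax.set_ylabel(r"allelic complexity $C_\mu$ [bits]")
    ax.legend(fontsize="x-small")
    return ax


def plot_stasis_times(summary_frame, ax=None, **plot_kw):
    """Mean time to stasis vs initial bias, with standard-error bars.

    Expects columns p0, mean, se (one row per initial-bias setting).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    ax.errorbar(
        summary_frame["p0"],
        summary_frame["mean"],
        yerr=summary_frame["se"],
        fmt="o-",
        capsize=3,
        **plot_kw,
    )
    ax.set_xlabel("initial bias Pr['1']")
    ax.set_ylabel("mean generations to stasis")
    return ax
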