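"""Minimal plotting helper: S(Q) curves with +/-1-sigma ribbons."""

from __future__ import annotations

from .estimators import PartialEstimate


def plot_estimate(est: PartialEstimate, ax=None, truth=None, logx: bool = True):
    """Plot each estimated partial function with a 1-sigma error ribbon.

    Parameters
    ----------
    est : PartialEstimate
    ax : matplotlib Axes, optional — created on demand.
    truth : TruePartials, optional — overplotted as dashed lines.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    q = est.qgrid.values
    for ell, label in enumerate(est.pair_labels):
        line, = ax.plot(q, est.means[ell], label=label)
        ax.fill_between(q, est.means[ell] - est.stderr[ell],
                        est.means[ell] + est.stderr[ell],
                        alpha=0.25, color=line.get_color())
    if truth is not None:
        for row in truth.s:
            ax.plot(truth.qgrid.values, row, "k--", lw=0.8)
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(r"$Q$ [$\mathrm{\AA}^{-1}$]")
    ax.set_ylabel(r"$S(Q)$")
    ax.legend()
    return ax
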