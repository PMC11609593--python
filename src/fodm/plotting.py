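"""Profile plots: T (blue), O (red), M (green) along the sequence."""

from __future__ import annotations

__all__ = ["plot_profiles"]

ROLE_COLORS = {"T": "tab:blue", "O": "tab:red", "M": "tab:green"}


def plot_profiles(results, ax=None, annotations: dict | None = None):
    """Line plot of the T, O and M profiles of a fitted unit.

    Parameters
    ----------
    results : FodResults
        A fitted assessment.
    ax : matplotlib axes, optional
        Target axes; a new figure is created when omitted.
    annotations : dict, optional
        ``{label: [0-based positions]}`` to mark along the x-axis
        (catalytic residues, interface residues, eliminated fragments —
        these are user-supplied, not computed).
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(9, 4))
    x = range(results.n_residues)
    ax.plot(x, results.t.values, color=ROLE_COLORS["T"], label="T (theoretical)")
    ax.plot(x, results.o.values, color=ROLE_COLORS["O"], label="O (observed)")
    ax.plot(x, results.m.values, color=ROLE_COLORS["M"], label=f"M (K={results.k:.2f})")
    if annotations:
        top = max(results.t.max_value, results.o.max_value)
        for i, (label, positions) in enumerate(annotations.items()):
            y = top * (1.05 + 0.05 * i)
            ax.plot(list(positions), [y] * len(positions), ".", label=label)
    ax.set_xlabel("residue (unit order)")
    ax.set_ylabel("normalized hydrophobicity")
    title = results.structure.unit_label or "structural unit"
    ax.set_title(f"{title}: RD={results.rd:.3f}, K={results.k:.2f}")
    ax.legend(loc="best", fontsize="small")
    return ax
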