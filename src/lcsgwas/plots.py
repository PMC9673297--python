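"""Minimal TSV-driven figure helpers (Manhattan and LD-decay plots)."""

from __future__ import annotations


def manhattan(summary, threshold: float | None = None, ax=None):
    """Manhattan plot from a GWAS summary frame (chrom, pos, neglog10_p)."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(summary.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, grp["neglog10_p"], s=4, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max()
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", ls="--", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10(P)")
    return ax


def ld_decay(curve, ax=None):
    """LD-decay plot from an :class:`~lcsgwas.ld.LDDecayCurve`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    df = curve.to_frame().dropna()
    mid = (df["bin_start"] + df["bin_end"]) / 2
    ax.plot(mid / 1000, df["mean_r2"])
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean r$^2$")
    return ax
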