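"""Per-chromosome scan figure: F_ST track plus sex-patterned allele
frequency tracks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .pool_diff import per_site_fst  # noqa: E402


def fst_scan_plot(classifications, out_path, chrom=None):
    """Three-panel scan: per-site F_ST, Y-allele (XY-patterned) frequency in
    the male pool and W-allele (ZW-patterned) frequency in the female pool.

    ``chrom`` restricts the plot to one chromosome; otherwise all sites are
    drawn on a shared axis in table order.
    """
    df = classifications
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    site_fst = per_site_fst(df)
    xy = df[df["label"] == "XY"]
    zw = df[df["label"] == "ZW"]

    fig, axes = plt.subplots(3, 1, figsize=(10, 6), sharex=True)
    axes[0].plot(site_fst["pos"], site_fst["fst"], ".", ms=2, color="gray")
    axes[0].set_ylabel("$F_{ST}$")
    axes[0].set_ylim(-0.05, 1.05)
    axes[1].plot(xy["pos"], xy["freq_male"], ".", ms=3, color="tab:blue")
    axes[1].set_ylabel("Y allele freq (M pool)")
    axes[1].set_ylim(-0.05, 1.05)
    axes[2].plot(zw["pos"], zw["freq_female"], ".", ms=3, color="tab:red")
    axes[2].set_ylabel("W allele freq (F pool)")
    axes[2].set_ylim(-0.05, 1.05)
    axes[2].set_xlabel(f"position on {chrom}" if chrom else "position (bp)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
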