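"""Quick-look plots (UV/ECD chromatograms, simulated spectra).

Matplotlib is imported lazily so the analysis pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

__all__ = ["plot_chromatogram", "plot_spectrum"]


def plot_chromatogram(chrom, axes=None, peaks=None):
    """Stacked UV (top) and ECD (bottom) traces; optional detected peaks."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax_uv, ax_ecd = axes
    ax_uv.plot(chrom.time, chrom.uv, lw=0.8, color="tab:blue")
    ax_uv.set_ylabel("UV / mAU")
    ax_ecd.plot(chrom.time, chrom.ecd, lw=0.8, color="tab:red")
    ax_ecd.axhline(0.0, color="0.7", lw=0.5)
    ax_ecd.set_ylabel("ECD / mdeg")
    ax_ecd.set_xlabel("time / min")
    if peaks:
        for p in peaks:
            ax_uv.axvspan(p.t_start, p.t_end, alpha=0.15, color="tab:green")
            ax_uv.axvline(p.rt, color="tab:green", lw=0.6)
    ax_uv.set_title(f"{chrom.meta.get('sample_id', '')} ({chrom.wavelength:g} nm)".strip())
    return axes


def plot_spectrum(spectrum, ax=None, label=None):
    """Simulated Δε(λ) curve with a zero line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(spectrum.wavelength, spectrum.delta_epsilon, label=label)
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.set_xlabel("wavelength / nm")
    ax.set_ylabel(r"$\Delta\epsilon$ / L mol$^{-1}$ cm$^{-1}$")
    if label:
        ax.legend()
    return ax
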