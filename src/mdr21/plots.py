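"""Basic frequency plot: per-cohort gain (up) and deletion (down) tracks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .harmonization import FrequencyProfile

__all__ = ["plot_frequency_profiles"]


def plot_frequency_profiles(
    profiles: list[FrequencyProfile], path: str | Path, regions=None
) -> None:
    """Stacked per-cohort panels; amplification up in blue, deletion down in
    red; optional detected regions shaded."""
    fig, axes = plt.subplots(
        len(profiles), 1, figsize=(10, 1.8 * len(profiles)),
        sharex=True, squeeze=False,
    )
    for ax, profile in zip(axes[:, 0], profiles):
        mb = profile.grid.positions / 1e6
        ax.fill_between(mb, 0, profile.amp_freq, color="tab:blue", lw=0)
        ax.fill_between(mb, 0, -profile.del_freq, color="tab:red", lw=0)
        ax.set_ylim(-1, 1)
        ax.set_ylabel(profile.cohort, rotation=0, ha="right", va="center")
        ax.axhline(0, color="black", lw=0.5)
        if regions:
            for r in regions:
                ax.axvspan(r.start_bp / 1e6, r.end_bp / 1e6,
                           color="grey", alpha=0.2)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle("copy-number frequency (gain up, deletion down)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
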