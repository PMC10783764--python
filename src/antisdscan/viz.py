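"""Static histogram rendering of anti-SD profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .profiles import AntiSDProfile


def plot_profile(profile: AntiSDProfile, path, mode_fraction: float = 0.4):
    """Bar histogram of per-position interaction frequencies in central-U
    coordinates, with the mode-fraction cutoff line and the profile span
    highlighted."""
    positions = list(profile.freq)
    freqs = [profile.freq[p] for p in positions]
    first, last = profile.span
    colors = [
        "tab:green" if first <= p <= last else "tab:gray" for p in positions
    ]
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.bar(positions, freqs, color=colors, width=0.8)
    ax.axhline(
        mode_fraction * profile.mode_freq,
        color="tab:red", linestyle="--", linewidth=1,
        label=f"{mode_fraction:g} x mode",
    )
    ax.set_xlabel("tail position relative to central U of CCUCC")
    ax.set_ylabel("fraction of mRNAs pairing")
    ax.set_title(
        f"{profile.profile_id}: antiSD {profile.consensus} "
        f"({first:+d}..{last:+d}), {profile.pct_sd:.1f}% SD"
    )
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
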