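"""30-channel 10-20 montage and scalp-region groupings.

The acquisition montage has 32 positions; A1/A2 are the linked-mastoid
reference pair and are excluded from analysis, leaving the 30 scalp
channels below (the recording hardware reports "30 electrodes" for the
same reason).
"""

from __future__ import annotations

CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)

OCCIPITAL_CHANNELS: tuple[str, ...] = ("O1", "O2", "Oz")

# Non-overlapping scalp regions used for nodal summaries. Standard 10-20
# laterality is used throughout (odd = left, even = right), even where
# narrative descriptions elsewhere occasionally swap sides.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "fronto_central": ("FC5", "FC1", "FC2", "FC6"),
    "central": ("C3", "Cz", "C4"),
    "left_temporal": ("T7",),
    "right_temporal": ("T8",),
    "centro_parietal": ("CP5", "CP1", "CP2", "CP6"),
    "parietal": ("P7", "P3", "Pz", "P4", "P8"),
    "occipital": ("PO3", "PO4", "O1", "Oz", "O2"),
}


def channel_index(label: str, channels: tuple[str, ...] = CHANNELS_10_20) -> int:
    """Index of *label* in the montage; raises ValueError with the label named."""
    try:
        return channels.index(label)
    except ValueError:
        raise ValueError(f"channel {label!r} is not in the montage") from None
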