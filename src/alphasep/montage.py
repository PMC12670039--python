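"""Electrode montage: channel names, hemispheric groups, and the stimulation cluster.

Channel side is inferred from the 10-20 naming convention: labels ending in an
odd digit are left-hemisphere, even digits right-hemisphere, and a trailing
``z`` marks the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Posterior electrode groups used for the lateralisation (modulation index)
#: analysis in 64-channel-style montages.
LEFT_POSTERIOR = ("O1", "P3", "P7", "PO3", "PO7")
RIGHT_POSTERIOR = ("O2", "P4", "P8", "PO4", "PO8")

#: Right posterior cluster around the TMS stimulation site.
STIM_CLUSTER = (
    "P2", "P4", "P6", "P8", "PO4", "PO8", "O2",
    "CP2", "CP4", "CP6", "TP8", "C2", "C4", "C6", "T8",
)

#: Default 30-channel geometry: the full right stimulation cluster, left-side
#: mirrors of 13 of its electrodes, and two midline references.
DEFAULT_CHANNELS = (
    "O1", "P1", "P3", "P5", "P7", "PO3", "PO7",
    "CP1", "CP3", "CP5", "TP7", "C3", "T7",
    "Cz", "Pz",
    "O2", "P2", "P4", "P6", "P8", "PO4", "PO8",
    "CP2", "CP4", "CP6", "TP8", "C2", "C4", "C6", "T8",
)


def channel_side(name: str) -> str:
    """Return ``"left"``, ``"right"`` or ``"midline"`` for a 10-20 label."""
    tail = name[-1]
    if tail in "zZ":
        return "midline"
    if tail.isdigit():
        return "left" if int(tail) % 2 == 1 else "right"
    return "midline"


class MontageError(ValueError):
    """Raised when electrode groups are inconsistent with the channel list."""


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus the electrode groups the analyses need.

    Parameters
    ----------
    channel_names
        All channels, in the order they appear in the data tensor.
    left_posterior, right_posterior
        Posterior electrode groups entering the per-hemisphere modulation
        index.
    stim_cluster
        Right posterior cluster over which TMS modulation effects are
        averaged.
    """

    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    left_posterior: tuple[str, ...] = LEFT_POSTERIOR
    right_posterior: tuple[str, ...] = RIGHT_POSTERIOR
    stim_cluster: tuple[str, ...] = STIM_CLUSTER
    channel_sides: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        names = set(self.channel_names)
        if len(names) != len(self.channel_names):
            raise MontageError("duplicate channel names")
        if set(self.left_posterior) & set(self.right_posterior):
            raise MontageError("left and right posterior groups overlap")
        for group, label in (
            (self.left_posterior, "left_posterior"),
            (self.right_posterior, "right_posterior"),
            (self.stim_cluster, "stim_cluster"),
        ):
            missing = set(group) - names
            if missing:
                raise MontageError(f"{label} channels not in montage: {sorted(missing)}")
        if not self.channel_sides:
            object.__setattr__(
                self,
                "channel_sides",
                tuple(channel_side(c) for c in self.channel_names),
            )
        elif len(self.channel_sides) != len(self.channel_names):
            raise MontageError("channel_sides length must match channel_names")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def indices(self, names: tuple[str, ...] | list[str]) -> list[int]:
        """Indices of ``names`` in the montage's channel order."""
        lookup = {c: i for i, c in enumerate(self.channel_names)}
        try:
            return [lookup[n] for n in names]
        except KeyError as err:
            raise MontageError(f"channel {err.args[0]!r} not in montage") from None


def default_montage() -> Montage:
    """The package's 30-channel default montage."""
    return Montage()
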