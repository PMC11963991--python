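"""Channel layout of the five-pad trimodal device.

The device carries five sensing pads, each with a 6-axis inertial unit
(3-axis acceleration in m/s^2, 3-axis rotation in degrees per second) plus
ECG electrodes (mV).  Pad 5 sits over the heart and acquires the cardiac
mechanical signals (SCG on its accelerometer, GCG on its gyroscope); pads
1-4 sit on the periphery and record mostly body motion, serving as
reference channels for artifact compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AXES = ("X", "Y", "Z")
MODALITIES = ("Acc", "Rot")

ACC_UNIT = "m/s^2"
ROT_UNIT = "dps"
ECG_UNIT = "mV"


def _mech_channel_names(pad_count: int) -> list[str]:
    return [
        f"Pad{i}.{mod}.{ax}"
        for i in range(1, pad_count + 1)
        for mod in MODALITIES
        for ax in AXES
    ]


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel naming scheme for a recording.

    Mechanical channels are named ``Pad{i}.Acc.{X|Y|Z}`` and
    ``Pad{i}.Rot.{X|Y|Z}`` for pads ``1..pad_count`` (30 channels for the
    default five-pad device), followed by the ECG channel(s).
    """

    pad_count: int = 5
    ecg_channels: tuple[str, ...] = ("ECG",)
    acquisition_pad: int = 5
    compensation_pads: tuple[int, ...] = (1, 2, 3, 4)
    mech_channels: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if self.pad_count < 1:
            raise ValueError("pad_count must be >= 1")
        if not 1 <= self.acquisition_pad <= self.pad_count:
            raise ValueError("acquisition_pad outside 1..pad_count")
        if self.acquisition_pad in self.compensation_pads:
            raise ValueError("acquisition_pad cannot also be a compensation pad")
        if any(not 1 <= p <= self.pad_count for p in self.compensation_pads):
            raise ValueError("compensation pad index outside 1..pad_count")
        object.__setattr__(
            self, "mech_channels", tuple(_mech_channel_names(self.pad_count))
        )
        names = self.mech_channels + tuple(self.ecg_channels)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def channels(self) -> tuple[str, ...]:
        """All channel names, mechanical first, in acquisition order."""
        return self.mech_channels + tuple(self.ecg_channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def pad_channels(self, pad: int, modality: str | None = None) -> list[str]:
        """Channel names of one pad, optionally restricted to Acc or Rot."""
        mods = (modality,) if modality else MODALITIES
        return [f"Pad{pad}.{m}.{ax}" for m in mods for ax in AXES]

    def unit(self, name: str) -> str:
        if name in self.ecg_channels:
            return ECG_UNIT
        return ACC_UNIT if ".Acc." in name else ROT_UNIT

    def validate_names(self, names) -> None:
        """Raise if ``names`` is not exactly this layout's channel set in order."""
        if tuple(names) != self.channels:
            raise ValueError(
                f"channel names do not match layout ({len(tuple(names))} given, "
                f"{self.n_channels} expected)"
            )
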