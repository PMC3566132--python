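"""Acquisition geometry shared by the simulator and the quantification stages."""

from __future__ import annotations

from dataclasses import dataclass, field

#: µm per pixel with a 20×/0.5 NA objective and 2×2 camera binning.
PIXEL_PITCH_20X_UM = 0.6848
#: µm per pixel with a 40×/0.75 NA objective and 2×2 camera binning.
PIXEL_PITCH_40X_UM = 0.344

DEFAULT_CHANNELS = ("nuclei", "lipid", "protein1", "protein2")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Pixel calibration and image geometry of one acquisition setting.

    ``pixel_pitch_um`` converts mask pixel counts into areas (µm²/cell); it is
    the only place physical units enter the pipeline.
    """

    pixel_pitch_um: float = PIXEL_PITCH_20X_UM
    image_width_px: int = 512
    image_height_px: int = 512
    bit_depth: int = 16
    channel_names: tuple[str, str, str, str] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")
        if self.image_width_px < 64 or self.image_height_px < 64:
            raise ValueError("image dimensions must be at least 64 px")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if len(self.channel_names) != 4:
            raise ValueError("exactly 4 channel names are required")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch_um ** 2

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) — 0-based, row-major, origin top-left."""
        return (self.image_height_px, self.image_width_px)

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_pitch_um
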