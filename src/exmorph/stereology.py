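"""Optical-fractionator estimation of total neuron number.

Design-based stereology: neurons are counted (ΣQ⁻) in optical dissectors
placed on a systematic random grid over a systematic subsample of sections,
and the total is estimated by dividing by the three sampling fractions

    N̂ = ΣQ⁻ · (1/ssf) · (1/asf) · (1/tsf)

with section sampling fraction ssf = 1/section_interval, area sampling
fraction asf = frame_area / (grid_step_x · grid_step_y), and thickness
sampling fraction tsf = dissector_height / mean_section_thickness. The guard
zone offset from the section top is recorded as metadata only — it does not
enter the estimator, which uses just the dissector height and the measured
mounted-section thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FractionatorDesign", "CountRecord", "estimate_total"]


@dataclass
class FractionatorDesign:
    """Sampling design of an optical-fractionator study.

    Defaults follow a common midbrain dopamine-neuron design: every 6th
    section, a 60×60 µm² counting frame on a 150 µm grid, a 10 µm dissector
    with a 2 µm guard zone.
    """

    section_interval: int = 6  # count every section_interval-th section
    frame_area: float = 60.0 * 60.0  # µm², counting frame
    grid_step: tuple[float, float] = (150.0, 150.0)  # (x, y) µm between sites
    dissector_height: float = 10.0  # µm
    mean_section_thickness: float = 20.0  # µm, measured mounted thickness
    guard_zone: float = 2.0  # µm from section top; metadata only

    def __post_init__(self) -> None:
        gx, gy = self.grid_step
        if min(self.section_interval, self.frame_area, gx, gy, self.dissector_height, self.mean_section_thickness) <= 0:
            raise ValueError("all design parameters must be positive")
        if self.dissector_height > self.mean_section_thickness:
            raise ValueError("dissector height exceeds section thickness")
        if self.frame_area > gx * gy:
            raise ValueError("counting frame larger than grid cell")

    @property
    def inverse_sampling_fraction(self) -> float:
        """The multiplier taking ΣQ⁻ to the total estimate."""
        gx, gy = self.grid_step
        return (
            self.section_interval
            * (gx * gy / self.frame_area)
            * (self.mean_section_thickness / self.dissector_height)
        )


@dataclass
class CountRecord:
    """Raw dissector counts (ΣQ⁻) for one anatomical region."""

    region: str
    raw_count: int

    def __post_init__(self) -> None:
        if self.raw_count < 0 or int(self.raw_count) != self.raw_count:
            raise ValueError(f"raw_count must be a non-negative integer, got {self.raw_count}")
        self.raw_count = int(self.raw_count)


def estimate_total(
    counts: list[CountRecord], design: FractionatorDesign
) -> dict[str, float]:
    """Per-region and combined total-number estimates.

    Returns a mapping region → N̂ plus a ``"combined"`` entry summing all
    regions (e.g. SNc + VTA for the whole midbrain dopamine population).
    """
    factor = design.inverse_sampling_fraction
    estimates: dict[str, float] = {}
    for record in counts:
        estimates[record.region] = estimates.get(record.region, 0.0) + record.raw_count * factor
    estimates["combined"] = sum(estimates.values())
    return estimates
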