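"""Frequency-band definitions for the magnetometer filter bank.

The default bank covers the five classical bands used for sensor-level
band-power features: delta (1-4 Hz), theta (5-8 Hz), alpha (9-14 Hz),
beta (15-30 Hz) and gamma (31-45 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def validate_against(self, fs: float) -> None:
        """Raise if the band (including filter transitions) touches 0 or Nyquist."""
        from .features import _transition_width  # local import, no cycle at module load

        nyq = fs / 2.0
        tw_lo = _transition_width(self.f_lo)
        tw_hi = _transition_width(self.f_hi)
        if self.f_lo - tw_lo / 2.0 <= 0.0:
            raise ValueError(f"band {self.name!r} overlaps 0 Hz after transition")
        if self.f_hi + tw_hi / 2.0 >= nyq:
            raise ValueError(f"band {self.name!r} overlaps Nyquist ({nyq} Hz)")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 5.0, 8.0),
    BandDefinition("alpha", 9.0, 14.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("gamma", 31.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def bands_from_yaml(path) -> tuple[BandDefinition, ...]:
    """Load a band bank from YAML: a list of ``{name, f_lo, f_hi}`` mappings."""
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{path}: expected a non-empty list of band mappings")
    return tuple(
        BandDefinition(e["name"], float(e["f_lo"]), float(e["f_hi"])) for e in entries
    )
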