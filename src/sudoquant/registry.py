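"""Reference-test registry: which neuropathy measure is called abnormal, and when.

Each entry dichotomizes a continuous reference measure with a strict
inequality: ``direction="below"`` means *abnormal if value < threshold*,
``direction="above"`` means *abnormal if value > threshold*.  Values exactly
at the threshold are normal.  The defaults are the conventional clinical
cut-offs for each measure (e.g. peroneal motor conduction velocity abnormal
below 42 m/s, Neuropathy Disability Score abnormal above 2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

_DIRECTIONS = ("below", "above")


@dataclass(frozen=True)
class ReferenceTest:
    """A dichotomization rule for one reference neuropathy measure.

    Parameters
    ----------
    measure
        Column name of the measure (e.g. ``"PMNCV"``).
    threshold
        Cut-off value in the measure's native units.
    direction
        ``"below"`` (abnormal if value < threshold) or ``"above"``
        (abnormal if value > threshold).  Strict in both cases.
    units
        Human-readable units, informational only.
    """

    measure: str
    threshold: float
    direction: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ConfigError(
                f"registry.{self.measure}.direction must be one of {_DIRECTIONS}, "
                f"got {self.direction!r}"
            )

    def is_abnormal(self, value: float) -> bool:
        """Apply the strict-inequality rule to a single value."""
        if self.direction == "below":
            return value < self.threshold
        return value > self.threshold


def default_registry() -> dict[str, ReferenceTest]:
    """Clinical cut-offs for the twelve reference neuropathy measures."""
    entries = [
        ReferenceTest("NDS", 2.0, "above", "score 0-10"),
        ReferenceTest("VPT", 14.0, "above", "V"),
        ReferenceTest("SNAP", 3.0, "below", "uV"),
        ReferenceTest("SNCV", 43.0, "below", "m/s"),
        ReferenceTest("PMNAP", 2.0, "below", "uV"),
        ReferenceTest("PMNCV", 42.0, "below", "m/s"),
        ReferenceTest("IENFD", 4.0, "below", "fibres/mm"),
        ReferenceTest("CNFD", 24.0, "below", "fibres/mm^2"),
        ReferenceTest("CNBD", 18.0, "below", "branches/mm^2"),
        ReferenceTest("CNFL", 14.0, "below", "mm/mm^2"),
        ReferenceTest("DB_HRV", 10.0, "below", "beats/min"),
        ReferenceTest("WPT", 42.0, "above", "degC"),
    ]
    return {t.measure: t for t in entries}
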