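"""Karyotype and sample-metadata domain types.

A karyotype is encoded by its sex-chromosome copy numbers (n_x, n_y).  The
expected number of inactivated X chromosomes follows Ohno's n-1 rule: every
X beyond the first is silenced, so the expected Xi count is ``n_x - 1`` and
the XIST dose scales with it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["KaryotypeSpec", "SampleMeta", "parse_karyotype_label"]

_LABEL_RE = re.compile(r"^\s*(\d+)\s*,\s*(X+)(Y*)\s*$")


@dataclass(frozen=True)
class KaryotypeSpec:
    """Sex-chromosome copy numbers driving every dosage law.

    Parameters
    ----------
    n_x : number of X chromosomes (>= 1)
    n_y : number of Y chromosomes (>= 0)
    label : display string such as ``"47,XXY"``; auto-derived if empty.
    """

    n_x: int
    n_y: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_x < 1:
            raise ValueError(f"n_x must be >= 1, got {self.n_x}")
        if self.n_y < 0:
            raise ValueError(f"n_y must be >= 0, got {self.n_y}")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())
        else:
            m = _LABEL_RE.match(self.label)
            if m:
                total = int(m.group(1))
                if total != 44 + self.n_x + self.n_y:
                    raise ValueError(
                        f"label {self.label!r} implies {total} chromosomes but "
                        f"(n_x={self.n_x}, n_y={self.n_y}) implies "
                        f"{44 + self.n_x + self.n_y}"
                    )

    def default_label(self) -> str:
        return f"{44 + self.n_x + self.n_y},{'X' * self.n_x}{'Y' * self.n_y}"

    @property
    def n_sex_chromosomes(self) -> int:
        return self.n_x + self.n_y

    @property
    def n_inactive_x(self) -> int:
        """Expected count of inactivated X chromosomes (Ohno's n-1 rule)."""
        return self.n_x - 1


def parse_karyotype_label(label: str) -> KaryotypeSpec:
    """Parse a karyotype display string like ``"47,XXY"`` or ``"XXXXY"``."""
    m = _LABEL_RE.match(label)
    if m is None:
        m2 = re.match(r"^\s*(X+)(Y*)\s*$", label)
        if m2 is None:
            raise ValueError(f"unparseable karyotype label: {label!r}")
        return KaryotypeSpec(n_x=len(m2.group(1)), n_y=len(m2.group(2)))
    n_x, n_y = len(m.group(2)), len(m.group(3))
    return KaryotypeSpec(n_x=n_x, n_y=n_y, label=label.strip())


@dataclass
class SampleMeta:
    """Per-sample metadata: karyotype and cohort role."""

    sample_id: str
    karyotype: KaryotypeSpec
    cohort_role: str = "case"  # {case, control_male, control_female}
    clone_id: str | None = None
    extras: dict = field(default_factory=dict)

    _ROLES = ("case", "control_male", "control_female")

    def __post_init__(self) -> None:
        if self.cohort_role not in self._ROLES:
            raise ValueError(
                f"cohort_role must be one of {self._ROLES}, got {self.cohort_role!r}"
            )
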