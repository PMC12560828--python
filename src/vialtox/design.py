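"""Experimental-design and ground-truth descriptors for the vial screen.

A screen exposes embryos to a dilution series in sealed rotating glass
vials; each treatment (chemical x concentration) is replicated over a
small number of vials, each holding a fixed number of embryos.  The
default design is six nominal water concentrations (a control plus five
doses up to 50 uM) with 4 vials x 8 embryos = 32 embryos per treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ScreenDesign", "TruthParams", "AssaySchedule", "DEFAULT_ENDPOINTS"]

#: Binary morphology endpoint codes; "ANY" is the composite any-effect endpoint.
DEFAULT_ENDPOINTS = ("MO24", "MORT", "CRAN", "AXIS", "EDEM", "MUSC", "LTRK", "ANY")


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a single-chemical concentration-response exposure.

    Parameters
    ----------
    concentrations : tuple of float
        Nominal water concentrations in uM.  Must be nonnegative,
        strictly increasing, and include the 0 uM control.
    vials_per_treatment : int
        Replicate vials per treatment group.
    embryos_per_vial : int
        Embryos loaded into each vial.
    endpoints : tuple of str
        Endpoint codes scored per embryo.
    """

    concentrations: tuple = (0.0, 3.125, 6.25, 12.5, 25.0, 50.0)
    vials_per_treatment: int = 4
    embryos_per_vial: int = 8
    endpoints: tuple = ("ANY",)

    def __post_init__(self):
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        if len(conc) < 2:
            raise ValueError("need at least a control and one positive dose")
        if conc[0] != 0.0:
            raise ValueError("concentrations must include the 0 uM control first")
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be nonnegative")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if self.vials_per_treatment * self.embryos_per_vial <= 0:
            raise ValueError("vials_per_treatment x embryos_per_vial must be positive")

    @property
    def embryos_per_treatment(self) -> int:
        return self.vials_per_treatment * self.embryos_per_vial


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters for the synthetic screen (ground truth).

    ``g`` is the background any-effect probability; ``bmc50_true`` the
    concentration producing 50% extra risk; ``slope_b`` the log-logistic
    slope; ``sigma_vial`` the SD of the vial random intercept on the
    logit scale.  ``lpr_effect`` is the additive shift applied to the
    dark-period log-movement mean in affected treatments; ``uptake_true``
    the per-embryo uptake ratio (nmol in fish per nmol nominally
    available); ``measurement_cv`` the multiplicative relative SD of the
    analytical measurement.
    """

    g: float = 0.05
    bmc50_true: float = 20.0
    slope_b: float = 4.0
    sigma_vial: float = 0.0
    lpr_effect: float = 0.0
    uptake_true: float = 0.13
    measurement_cv: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.g < 1.0:
            raise ValueError("background g must lie in [0, 1)")
        if self.bmc50_true <= 0:
            raise ValueError("bmc50_true must be positive")
        if self.slope_b <= 0:
            raise ValueError("slope_b must be positive")
        if self.sigma_vial < 0:
            raise ValueError("sigma_vial must be nonnegative")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be nonnegative")


def _default_epochs():
    # minutes 6-24 tracked, tiled as 3 cycles of 3-min light + 3-min dark
    out = []
    t = 360
    for _ in range(3):
        out.append(("light", t, t + 180))
        out.append(("dark", t + 180, t + 360))
        t += 360
    return tuple(out)


@dataclass(frozen=True)
class AssaySchedule:
    """Light/dark epoch layout of the larval photomotor assay.

    The tracked window defaults to minutes 6-24 (seconds 360-1440),
    tiled by alternating 3-minute light and dark epochs; the first
    light+dark pair after calibration is the cycle used for AUC.
    """

    tracked_window: tuple = (360, 1440)
    epochs: tuple = field(default_factory=_default_epochs)
    bin_seconds: float = 6.0

    def __post_init__(self):
        lo, hi = self.tracked_window
        if hi <= lo:
            raise ValueError("tracked window must have positive length")
        # epochs must tile the window without overlap
        t = lo
        for period, start, end in self.epochs:
            if period not in ("light", "dark"):
                raise ValueError(f"unknown period {period!r}")
            if start != t or end <= start:
                raise ValueError("epochs must tile the tracked window without gaps")
            t = end
        if t != hi:
            raise ValueError("epochs must cover the tracked window exactly")

    @property
    def first_cycle(self) -> tuple:
        """The (light, dark) epoch pair used for AUC."""
        light = next(e for e in self.epochs if e[0] == "light")
        dark = next(e for e in self.epochs if e[0] == "dark" and e[1] >= light[2])
        return light, dark

    def bin_starts(self):
        import numpy as np

        lo, hi = self.tracked_window
        return np.arange(lo, hi, self.bin_seconds)
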