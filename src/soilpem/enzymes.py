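"""Fluorometric enzyme activities and ecoenzymatic stoichiometry.

Five hydrolases index microbial resource acquisition: BG and CBH (carbon),
NAG and LAP (nitrogen), ALP (phosphorus).  Their stoichiometry is
summarized two ways:

* log-ratios E_C:N = ln(BG+CBH)/ln(NAG+LAP), E_C:P = ln(BG+CBH)/ln(ALP),
  E_N:P = ln(NAG+LAP)/ln(ALP);
* a vector model on the point (x, y) with x = (BG+CBH)/((BG+CBH)+ALP)
  (C vs P acquisition share) and y = (BG+CBH)/((BG+CBH)+(NAG+LAP))
  (C vs N share).  Vector length sqrt(x^2 + y^2) indexes carbon
  limitation; the vector angle - degrees of atan2(y, x) measured from the
  x-axis - indexes nutrient limitation: above 45 deg phosphorus-limited,
  below 45 deg nitrogen-limited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import EnzymeActivityTable, SampleMetadata
from .stats import duncan_letters

__all__ = [
    "PlateLayout", "fluorescence_to_activity", "EnzymeRatios", "enzyme_ratios",
    "EnzymeVector", "enzyme_vector", "stoichiometry_table", "vector_summary",
]


@dataclass
class PlateLayout:
    """One substrate's wells on a fluorometric microplate.

    Fluorescence readings are arbitrary fluorometer units.  ``assay`` wells
    hold soil homogenate plus substrate; ``blank`` wells homogenate plus
    buffer; ``quench_standard`` wells homogenate plus standard;
    ``negative_control`` wells buffer plus substrate; ``reference_standard``
    wells buffer plus standard.
    """

    assay: float
    blank: float
    quench_standard: float
    negative_control: float
    reference_standard: float
    incubation_time: float        # h
    soil_mass: float              # g dry soil
    homogenate_volume: float      # mL of soil suspension
    aliquot_volume: float = 200.0  # uL homogenate per well
    standard_amount: float = 0.5   # nmol standard per standard well

    def __post_init__(self) -> None:
        if self.incubation_time <= 0:
            raise ValueError("incubation time must be positive")
        if self.soil_mass <= 0:
            raise ValueError("soil mass must be positive")


def fluorescence_to_activity(plate: PlateLayout) -> float:
    """Convert plate fluorescence to activity in nmol h-1 g-1 dry soil.

    Net fluorescence = assay - blank - negative control; the emission
    coefficient (units per nmol) comes from the reference standard, the
    quench coefficient from the ratio of the homogenate standard to the
    buffer standard.  Negative net signal is floored at zero.
    """
    emission = plate.reference_standard / plate.standard_amount
    if emission <= 0:
        raise ValueError("degenerate standards: emission coefficient <= 0")
    quench = (plate.quench_standard - plate.blank) / plate.reference_standard
    if quench <= 0:
        raise ValueError("degenerate standards: quench coefficient <= 0")
    net = plate.assay - plate.blank - plate.negative_control * quench
    nmol = net / (emission * quench)
    per_well_soil = plate.soil_mass * (plate.aliquot_volume / 1000.0) / plate.homogenate_volume
    activity = nmol / (plate.incubation_time * per_well_soil)
    return max(activity, 0.0)


@dataclass
class EnzymeRatios:
    ec_n: float
    ec_p: float
    en_p: float
    flagged: bool = False   # any log argument <= 1: ratio sign-unstable


def enzyme_ratios(row) -> EnzymeRatios:
    """Ecoenzymatic log-ratios for one sample (natural logarithms)."""
    bg_cbh = float(row["BG"]) + float(row["CBH"])
    nag_lap = float(row["NAG"]) + float(row["LAP"])
    alp = float(row["ALP"])
    if bg_cbh <= 1 or nag_lap <= 1 or alp <= 1:
        return EnzymeRatios(math.nan, math.nan, math.nan, flagged=True)
    return EnzymeRatios(
        ec_n=math.log(bg_cbh) / math.log(nag_lap),
        ec_p=math.log(bg_cbh) / math.log(alp),
        en_p=math.log(nag_lap) / math.log(alp),
    )


@dataclass
class EnzymeVector:
    x: float
    y: float
    length: float
    angle: float          # degrees in [0, 90]
    limitation: str       # N_limited | P_limited | balanced
    flagged: bool = False


def enzyme_vector(row) -> EnzymeVector:
    """Vector-model summary for one sample."""
    bg_cbh = float(row["BG"]) + float(row["CBH"])
    nag_lap = float(row["NAG"]) + float(row["LAP"])
    alp = float(row["ALP"])
    denom_x = bg_cbh + alp
    denom_y = bg_cbh + nag_lap
    if denom_x <= 0 or denom_y <= 0:
        return EnzymeVector(math.nan, math.nan, math.nan, math.nan,
                            "undefined", flagged=True)
    x = bg_cbh / denom_x
    y = bg_cbh / denom_y
    if x == 0.0 and y == 0.0:
        return EnzymeVector(x, y, 0.0, math.nan, "undefined", flagged=True)
    length = math.hypot(x, y)
    angle = math.degrees(math.atan2(y, x))
    if angle > 45.0:
        limitation = "P_limited"
    elif angle < 45.0:
        limitation = "N_limited"
    else:
        limitation = "balanced"
    return EnzymeVector(x, y, length, angle, limitation)


def stoichiometry_table(enzymes: EnzymeActivityTable) -> pd.DataFrame:
    """Per-sample ratios and vector traits appended to the activity table."""
    rows = {}
    for sid, row in enzymes.data.iterrows():
        r = enzyme_ratios(row)
        v = enzyme_vector(row)
        rows[sid] = {"EC_N": r.ec_n, "EC_P": r.ec_p, "EN_P": r.en_p,
                     "x": v.x, "y": v.y, "vector_length": v.length,
                     "vector_angle": v.angle, "limitation": v.limitation,
                     "flagged": r.flagged or v.flagged}
    return enzymes.data.join(pd.DataFrame.from_dict(rows, orient="index"))


def vector_summary(enzymes: EnzymeActivityTable, metadata: SampleMetadata,
                   alpha: float = 0.05) -> dict:
    """Treatment means +/- SE of vector length and angle with Duncan letters,
    plus the angle-on-length regression (slope sign and p-value).

    Flagged samples (undefined ratios/angles) are excluded from group means
    with a logged warning.
    """
    stoich = stoichiometry_table(enzymes)
    ok = stoich[~stoich["flagged"].astype(bool)]
    dropped = stoich.index.difference(ok.index).tolist()
    if dropped:
        import logging
        logging.getLogger(__name__).warning(
            "excluding flagged samples from vector summary: %s", dropped)
    treatments = metadata.treatments.loc[ok.index]
    out = {}
    for col in ("vector_length", "vector_angle"):
        res = duncan_letters(ok[col].to_numpy(), treatments.to_numpy(),
                             alpha=alpha)
        out[col] = res.table
    if ok["vector_length"].nunique() > 1:
        from scipy.stats import linregress
        slope, intercept, r, p, se = linregress(ok["vector_length"],
                                                ok["vector_angle"])
    else:
        slope = intercept = r = p = se = math.nan
    out["angle_on_length"] = {"slope": float(slope), "intercept": float(intercept),
                              "r": float(r), "p": float(p), "se": float(se)}
    return out
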