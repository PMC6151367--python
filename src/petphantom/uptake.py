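"""Lesion uptake configurations and ground-truth heterogeneity indices.

A lesion is one to three radioactivity-concentration compartments packed
inside an irregular shell.  Seven canonical layouts are supported:

    a, b, c : necrotic tissue (a zero-uptake compartment C0 inside C1) as a
              concentric core, an off-center blob, or an angular wedge;
    d, e    : heterogeneous multifocal uptake (one or two hot foci at C2
              inside C1, with C2 = 5 * C1 by default);
    f, g    : combined heterogeneity and necrosis (C0 + C1 + C2).

Ground-truth indices are computed from the nominal compartment
concentrations and volume fractions (the pre-blur composition of the
lesion), not from the noisy simulated image:

* COV_GS   - percent ratio of the population standard deviation to the mean
             of the concentration over the lesion volume;
* I_G-GS   - normalized Gini heterogeneity of the modality frequencies,
             (1 - sum p_i^2) * k / (k - 1) for k >= 2 modalities, 0 for k = 1,
             so that an even two-way split scores exactly 1;
* H_GS     - total heterogeneity, COV_GS * I_G-GS, in [0, 100] for the
             two-level C / 5C compositions used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LAYOUTS = ("a", "b", "c", "d", "e", "f", "g", "uniform")

#: layouts containing a necrotic (zero uptake) compartment
NECROTIC_LAYOUTS = frozenset({"a", "b", "c", "f", "g"})
#: layouts containing a hot C2 compartment
HOT_LAYOUTS = frozenset({"d", "e", "f", "g"})

_FRAC_TOL = 1e-9


@dataclass(frozen=True)
class UptakeConfig:
    """Compartmental composition of one lesion.

    ``volume_fractions`` are ordered to match :meth:`concentrations`:
    (C0, C1[, C2]) for necrotic layouts, (C1, C2) for purely multifocal
    layouts, (C1,) for ``uniform``.
    """

    layout: str
    c1: float
    volume_fractions: tuple[float, ...]
    c2: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}; expected one of {LAYOUTS}")
        if self.c1 <= 0:
            raise ValueError("c1 must be positive")
        fr = np.asarray(self.volume_fractions, dtype=float)
        if np.any(fr < 0):
            raise ValueError("volume fractions must be non-negative")
        if abs(fr.sum() - 1.0) > _FRAC_TOL:
            raise ValueError(f"volume fractions must sum to 1, got {fr.sum()!r}")
        if len(fr) != len(self.concentrations()):
            raise ValueError(
                f"layout {self.layout!r} has {len(self.concentrations())} "
                f"compartments but got {len(fr)} fractions"
            )

    @property
    def c2_effective(self) -> float:
        """C2; defaults to the 5*C1 constraint when not overridden."""
        return 5.0 * self.c1 if self.c2 is None else self.c2

    @property
    def has_necrosis(self) -> bool:
        return self.layout in NECROTIC_LAYOUTS

    def concentrations(self) -> np.ndarray:
        """Nominal compartment concentrations, ordered to match fractions."""
        if self.layout == "uniform":
            return np.array([self.c1])
        c = []
        if self.has_necrosis:
            c.append(0.0)
        c.append(self.c1)
        if self.layout in HOT_LAYOUTS:
            c.append(self.c2_effective)
        return np.array(c)

    def fractions(self) -> np.ndarray:
        return np.asarray(self.volume_fractions, dtype=float)

    def modalities(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct concentration values and their merged frequencies."""
        conc = self.concentrations()
        fr = self.fractions()
        vals, inv = np.unique(conc, return_inverse=True)
        merged = np.zeros(len(vals))
        np.add.at(merged, inv, fr)
        keep = merged > 0
        return vals[keep], merged[keep]

    def active_fraction(self) -> float:
        """Volume fraction with nonzero uptake (necrosis excluded)."""
        vals, fr = self.modalities()
        return float(fr[vals > 0].sum())

    def mean_active_concentration(self) -> float:
        """Mean concentration over the metabolically active volume."""
        vals, fr = self.modalities()
        act = vals > 0
        w = fr[act]
        return float((vals[act] * w).sum() / w.sum())


def compute_cov_gs(config: UptakeConfig) -> float:
    """Ground-truth uptake coefficient of variation, percent.

    Population standard deviation over all lesion voxels (volume-fraction
    weighted, necrosis included) divided by the mean, times 100.
    """
    vals, fr = config.modalities()
    mean = float((vals * fr).sum())
    if mean <= 0:
        raise ValueError("all-necrotic lesion: mean concentration is zero")
    var = float((fr * (vals - mean) ** 2).sum())
    return 100.0 * np.sqrt(var) / mean


def compute_gini_gs(config_or_fractions) -> float:
    """Normalized Gini heterogeneity of the modality frequencies.

    For k >= 2 modalities returns (1 - sum p_i^2) * k / (k - 1), which is 0
    when one modality fills the lesion and 1 when the k modalities occupy
    equal volumes; a single modality scores 0 by definition.
    """
    if isinstance(config_or_fractions, UptakeConfig):
        _, fr = config_or_fractions.modalities()
    else:
        fr = np.asarray(config_or_fractions, dtype=float)
        if np.any(fr < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(fr.sum() - 1.0) > _FRAC_TOL:
            raise ValueError(f"frequencies must sum to 1, got {fr.sum()!r}")
        fr = fr[fr > 0]
    k = len(fr)
    if k < 1:
        raise ValueError("at least one modality required")
    if k == 1:
        return 0.0
    return float((1.0 - np.sum(fr**2)) * k / (k - 1))


def compute_h_gs(cov: float, gini: float) -> float:
    """Total heterogeneity index: the product COV_GS * I_G-GS."""
    if cov < 0:
        raise ValueError("cov must be >= 0")
    if not (0.0 <= gini <= 1.0):
        raise ValueError("gini must be in [0, 1]")
    return float(cov * gini)


@dataclass
class LesionGroundTruth:
    """Everything known exactly about one synthetic lesion."""

    lesion_id: str
    shell_id: str
    v_gs: float  # cc, total lesion volume
    v_gs_active: float  # cc, necrosis excluded
    s_gs: float
    cov_gs: float  # percent
    gini_gs: float
    h_gs: float
    lb_gs: float
    layout: str
    seed: int
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_components(
        cls,
        lesion_id: str,
        shell_id: str,
        volume_cc: float,
        sphericity: float,
        config: UptakeConfig,
        background: float,
        seed: int,
        meta: dict | None = None,
    ) -> "LesionGroundTruth":
        cov = compute_cov_gs(config)
        gini = compute_gini_gs(config)
        if background <= 0:
            raise ValueError("background concentration must be positive")
        return cls(
            lesion_id=lesion_id,
            shell_id=shell_id,
            v_gs=volume_cc,
            v_gs_active=volume_cc * config.active_fraction(),
            s_gs=sphericity,
            cov_gs=cov,
            gini_gs=gini,
            h_gs=compute_h_gs(cov, gini),
            lb_gs=config.mean_active_concentration() / background,
            layout=config.layout,
            seed=seed,
            meta=dict(meta or {}),
        )
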