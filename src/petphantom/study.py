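"""The default study cohort: 38 lesions over 9 simulated acquisitions.

Five irregular shells (A-E) with fixed volume and sphericity targets are
reused across nine acquisitions, exactly as five physical moulds would be
refilled and rescanned: 20 lesions carry uniform uptake and 18 heterogeneous
uptake (necrosis and/or multifocal hot spots, C2 = 5*C1), with
lesion-to-background ratios spanning 4-27.  Shell shapes depend only on the
cohort seed and the shell identity, so the same mould reappears in every
acquisition; noise realizations differ per lesion and acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionSettings, default_settings, simulate_acquisition
from .phantom import Phantom, build_phantom, ground_truth
from .shells import Shell, ShellSpec, calibrate_amplitude, generate_shell
from .uptake import LesionGroundTruth, UptakeConfig
from .volume import ActivityVolume

#: shell targets: volume (cc), sphericity, harmonic band limit
SHELL_TARGETS = {
    "A": (6.8, 0.57, 8),
    "B": (10.5, 0.62, 8),
    "C": (8.5, 0.49, 14),
    "D": (12.5, 0.74, 8),
    "E": (32.3, 0.73, 8),
}

#: heterogeneous composition per shell: (layout, volume_fractions)
#: fractions ordered (C0, C1[, C2]) / (C1, C2) per the layout's compartments
HET_RECIPES = {
    "A": ("b", (0.06, 0.94)),  # off-center necrotic blob
    "B": ("d", (0.88, 0.12)),  # single hot focus
    "B2": ("e", (0.88, 0.12)),  # two hot foci
    "C": ("a", (0.13, 0.87)),  # concentric necrotic core
    "D": ("c", (0.064, 0.936)),  # necrotic wedge
    "D2": ("g", (0.20, 0.65, 0.15)),  # core + hot mid shell
    "E": ("f", (0.09, 0.76, 0.15)),  # core + hot focus
}

#: per-acquisition plan: (shell_id, uniform?, L/B target, het recipe key)
ACQUISITION_PLAN = {
    1: [("A", True, 10, None), ("B", True, 10, None), ("C", True, 10, None), ("D", True, 10, None)],
    2: [("A", True, 10, None), ("B", True, 10, None), ("C", True, 10, None), ("D", True, 10, None)],
    3: [("A", True, 10, None), ("B", True, 10, None), ("C", True, 10, None), ("D", True, 10, None)],
    4: [("A", True, 27, None), ("B", True, 26, None), ("C", False, 9, "C"), ("D", False, 25, "D")],
    5: [("A", True, 27, None), ("B", True, 26, None), ("C", False, 9, "C"), ("D", False, 25, "D")],
    6: [("A", True, 27, None), ("B", True, 26, None), ("C", False, 9, "C"), ("D", False, 25, "D")],
    7: [("A", True, 12, None), ("B", True, 11, None), ("C", False, 4, "C"), ("D", False, 11, "D")],
    8: [("A", False, 18, "A"), ("B", False, 10, "B"), ("C", False, 7, "C"),
        ("D", False, 9, "D2"), ("E", False, 25, "E")],
    9: [("A", False, 12, "A"), ("B", False, 7, "B2"), ("C", False, 5, "C"),
        ("D", False, 6, "D2"), ("E", False, 16, "E")],
}

#: background activity concentration by phantom compartment, MBq/cc
BACKGROUNDS = {"thorax": 0.006, "breast": 0.005, "lung": 0.004,
               "liver": 0.013, "myocardium": 0.023}


@dataclass
class LesionRecord:
    """One lesion of the cohort: rasterized phantom plus its ground truth."""

    lesion_id: str
    shell_id: str
    acquisition: int
    phantom: Phantom
    gt: LesionGroundTruth
    lb_target: float
    seed: int


def _shell_seed(master_seed: int, shell_id: str) -> int:
    return int(
        np.random.SeedSequence([master_seed, ord(shell_id)]).generate_state(1)[0]
        % (2**31)
    )


_shell_cache: dict[tuple, Shell] = {}


def make_shell(master_seed: int, shell_id: str, gs_resolution: float = 1.0) -> Shell:
    """Build shell `shell_id` at its volume and sphericity targets.

    The deformation amplitude is found by bisection against the sphericity
    target; the base radius is then rescaled so the mesh volume lands on the
    volume target (sphericity is scale-free, so the two are independent).
    """
    key = (master_seed, shell_id, gs_resolution)
    if key in _shell_cache:
        return _shell_cache[key]
    v_target, s_target, lmax = SHELL_TARGETS[shell_id]
    seed = _shell_seed(master_seed, shell_id)
    amp = calibrate_amplitude(seed, s_target, lmax=lmax)
    r0 = 12.0
    probe = generate_shell(
        ShellSpec(seed=seed, base_radius=r0, deformation_amplitude=amp,
                  resolution=gs_resolution, lmax=lmax)
    )
    radius = r0 * (v_target / probe.volume_cc) ** (1.0 / 3.0)
    shell = generate_shell(
        ShellSpec(seed=seed, base_radius=radius, deformation_amplitude=amp,
                  resolution=gs_resolution, lmax=lmax)
    )
    _shell_cache[key] = shell
    return shell


def _unit_mean_active_factor(layout: str, fractions: tuple[float, ...]) -> float:
    """mean active concentration per unit C1 for a layout/fraction choice."""
    probe = UptakeConfig(layout=layout, c1=1.0, volume_fractions=fractions)
    return probe.mean_active_concentration()


def build_cohort(
    seed: int,
    n_lesions: int = 38,
    gs_resolution: float = 1.0,
    background_compartment: str = "thorax",
) -> list[LesionRecord]:
    """Rasterize ``n_lesions`` lesions of the study plan.

    Smaller cohorts take an evenly spaced subset of the full 38-lesion plan,
    preserving the uniform/heterogeneous mix and the shell variety; lesion
    ids keep their position in the full plan.
    """
    plan = [
        (acq, item)
        for acq in sorted(ACQUISITION_PLAN)
        for item in ACQUISITION_PLAN[acq]
    ]
    n_lesions = min(n_lesions, len(plan))
    picks = sorted(set(np.linspace(0, len(plan) - 1, n_lesions).round().astype(int)))
    records: list[LesionRecord] = []
    count = 0
    for acq in sorted(ACQUISITION_PLAN):
        for shell_id, uniform, lb, recipe_key in ACQUISITION_PLAN[acq]:
            count += 1
            if count - 1 not in picks:
                continue
            lesion_id = f"L{count:02d}"
            shell = make_shell(seed, shell_id, gs_resolution)
            bg = BACKGROUNDS["breast" if shell_id == "E" else background_compartment]
            cfg_seed = int(
                np.random.SeedSequence([seed, acq, count]).generate_state(1)[0]
                % (2**31)
            )
            if uniform:
                cfg = UptakeConfig(layout="uniform", c1=lb * bg,
                                   volume_fractions=(1.0,), seed=cfg_seed)
            else:
                layout, fractions = HET_RECIPES[recipe_key]
                m = _unit_mean_active_factor(layout, fractions)
                cfg = UptakeConfig(layout=layout, c1=lb * bg / m,
                                   volume_fractions=fractions, seed=cfg_seed)
            phantom = build_phantom(shell, cfg, background=bg)
            gt = ground_truth(
                phantom, lesion_id, shell_id, cfg_seed,
                meta={"acquisition": acq, "lb_target": lb},
            )
            records.append(
                LesionRecord(
                    lesion_id=lesion_id, shell_id=shell_id, acquisition=acq,
                    phantom=phantom, gt=gt, lb_target=lb, seed=cfg_seed,
                )
            )
    return records


def build_study(
    seed: int,
    n_lesions: int = 38,
    settings: AcquisitionSettings | None = None,
    gs_resolution: float = 1.0,
) -> list[tuple[ActivityVolume, LesionGroundTruth]]:
    """Simulate the cohort at one acquisition setting.

    Returns (volume, ground truth) pairs; each lesion gets its own noise
    seed derived from the master seed.
    """
    if settings is None:
        settings = default_settings()
    out = []
    for rec in build_cohort(seed, n_lesions=n_lesions, gs_resolution=gs_resolution):
        lesion_seed = int(
            np.random.SeedSequence([seed, rec.acquisition, rec.seed]).generate_state(1)[0]
            % (2**31)
        )
        from dataclasses import replace

        vol = simulate_acquisition(rec.phantom, replace(settings, seed=lesion_seed))
        out.append((vol, rec.gt))
    return out
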