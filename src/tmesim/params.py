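"""Material parameters and simulation configuration.

The simulator tracks five diffusible factors -- oxygen, glucose, TGFα, TNFα
and VEGF -- on a lattice of tumor microenvironments (TMEs).  Each material
carries four physical constants: a normal tissue concentration ``c_normal``
(µM), a maximum concentration ``c_max`` (µM), a diffusion coefficient ``d``
(cm²/s) and a vessel-wall permeability ``rho`` (cm/s).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

#: Canonical material ordering used by every concentration array in the
#: package (axis 0 of the field lattice).
MATERIALS = ("oxygen", "glucose", "tgfa", "tnfa", "vegf")

OXYGEN, GLUCOSE, TGFA, TNFA, VEGF = range(5)

#: Cell phenotypes, in the order used for the VEGF-secretion and
#: nutrient-uptake tiers (2^0..2^4 and 2^4..2^0 respectively).
CELL_PHENOTYPES = ("proliferation", "migration", "quiescence", "hypoxia", "necrosis")
PROLIFERATION, MIGRATION, QUIESCENCE, HYPOXIA, NECROSIS = range(5)

#: Vessel phenotypes.  Stalk segments may never select ``branch``.
VESSEL_PHENOTYPES = ("quiescence", "branch", "sprout")
V_QUIESCENCE, V_BRANCH, V_SPROUT = range(3)


class ConfigurationError(ValueError):
    """Raised for invalid geometry or parameter combinations."""


@dataclasses.dataclass(frozen=True)
class MaterialParams:
    """Physical constants for one diffusible factor.

    ``c_normal``/``c_max`` may be ``None`` when the source table leaves the
    entry blank (VEGF); a blank ``c_max`` disables the upper clamp.
    """

    material: str
    c_normal: float | None  # µM
    c_max: float | None  # µM
    d: float  # cm²/s
    rho: float  # cm/s

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ConfigurationError(f"unknown material {self.material!r}")
        for name in ("c_normal", "c_max", "d", "rho"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(f"{self.material}.{name} must be >= 0, got {v}")
        if self.material in ("oxygen", "glucose") and self.c_max < self.c_normal:
            raise ConfigurationError(
                f"{self.material}: c_max ({self.c_max}) < c_normal ({self.c_normal})"
            )


def default_materials() -> dict[str, MaterialParams]:
    """The five-material parameter set used throughout the model."""
    table = {
        #            c_normal   c_max      D          rho
        "oxygen": (34.8, 55.6, 1.67e-7, 10.0),
        "glucose": (1.7e4, 5.7e4, 6.7e-7, 3.0e3),
        "tgfa": (2.0e-3, 90.1, 5.12e-7, 5.5e-2),
        "tnfa": (6.0e-3, 1.0e-6, 1.5e-7, 0.82),
        "vegf": (None, None, 2.9e-7, 1.0e3),
    }
    return {
        m: MaterialParams(m, *table[m]) for m in MATERIALS
    }


def validate_materials(materials: dict[str, MaterialParams]) -> None:
    if set(materials) != set(MATERIALS):
        raise ConfigurationError(
            f"a full parameter set needs exactly the five materials {MATERIALS}, "
            f"got {sorted(materials)}"
        )


#: Policy thresholds (Table-2 rules are defined in :mod:`tmesim.sarsa`; the
#: concentration thresholds live on a dimensionless "policy scale").
POLICY_THRESHOLDS = {
    "oxygen": 1.175,
    "glucose_active": 16.0,
    "glucose_dead": 8.0,
    "tnfa": 0.6,
    "tgfa": 0.6,
    "vegf": 0.3,
    "vessel_age": 18.0,
    "division_counter": 50.0,
    "proliferation_delay": 4.0,
    "oxygen_deficiency": 67.0,
}


def policy_scales(materials: dict[str, MaterialParams]) -> dict[str, float]:
    """Per-material divisors mapping raw µM onto the policy scale.

    The divisor is chosen so that the normal tissue concentration of a
    material lands at twice its rule threshold (a healthy TME sits safely on
    the "above" side of each rule).  VEGF has no tabulated normal
    concentration; its divisor is set so that the sprouting threshold
    separates the per-episode VEGF output of a normoxic TME at carrying
    capacity (100 cells x 2⁰ x 10⁻² = 1 µM) from that of a hypoxic or
    necrotic one (8-16 µM): with a divisor of 10 the threshold 0.3 sits at
    3 µM, between the two regimes.
    """
    t = POLICY_THRESHOLDS
    return {
        "oxygen": materials["oxygen"].c_normal / (2.0 * t["oxygen"]),
        "glucose": materials["glucose"].c_normal / (2.0 * t["glucose_active"]),
        "tgfa": materials["tgfa"].c_normal / (2.0 * t["tgfa"]),
        "tnfa": materials["tnfa"].c_normal / (2.0 * t["tnfa"]),
        "vegf": 10.0,
    }


@dataclasses.dataclass
class SimulationConfig:
    """Run geometry, timing and model constants.

    Defaults reproduce the full-scale study conditions: a 2 x 2 cm domain of
    10^4 TMEs of 200 x 200 µm, 1-h episodes for 720 h (30 d), 50 training
    repetitions and one million seeded cancer cells.
    """

    domain_cm: float = 2.0  # domain side length (cm)
    tme_um: float = 200.0  # TME side length (µm)
    dt_s: float = 3600.0  # episode duration (s)
    n_episodes: int = 720
    n_repetitions: int = 50
    initial_cells: int = 1_000_000
    carrying_capacity: int = 100  # cells per TME
    seed: int = 0
    sigma2: float = 0.3  # variance of the initialization distribution
    assimilation_episode: int = 336
    far_distance: float = 10.0  # d_TME sentinel (TME side lengths)
    eq1_use_dtme_for_growth_factors: bool = False
    # mesoscopic constants
    migration_um_per_episode: float = 45.0
    sprout_um_per_episode: float = 60.0
    division_period_h: int = 24  # proliferation episodes accumulated per division
    necrotic_removal_after: int | None = None
    # SARSA / dataset
    alpha: float = 0.1
    gamma: float = 0.9
    # dataset admission threshold on the transition reward; None records all
    # (sampled by quota), so the dataset mirrors the learned policy mixture
    reward_threshold: float | None = None
    record_quota_cells: int = 40  # transitions recorded per episode (cells)
    record_quota_vessels: int = 10
    # classifier
    hidden_layers: tuple[int, int] = (35, 25)
    nn_epochs: int = 200
    nn_learning_rate: float = 0.01
    fit_max_records: int = 50_000
    # signaling
    k_on: float = 1.0  # µM⁻¹ s⁻¹
    k_off: float = 1.0e-3  # s⁻¹
    materials: dict[str, MaterialParams] = dataclasses.field(
        default_factory=default_materials
    )

    def __post_init__(self) -> None:
        validate_materials(self.materials)
        if self.dt_s <= 0:
            raise ConfigurationError("episode duration dt_s must be > 0")
        for name in ("n_episodes", "n_repetitions", "initial_cells", "carrying_capacity"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.sigma2 <= 0:
            raise ConfigurationError("sigma2 must be > 0")
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.gamma <= 1.0):
            raise ConfigurationError("alpha and gamma must lie in [0, 1]")
        side_um = self.domain_cm * 1e4
        n = side_um / self.tme_um
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"domain side ({self.domain_cm} cm = {side_um} µm) is not divisible "
                f"by the TME side ({self.tme_um} µm)"
            )

    @property
    def grid_side(self) -> int:
        """Number of TMEs along one side of the square lattice."""
        return round(self.domain_cm * 1e4 / self.tme_um)

    @property
    def tme_area_cm2(self) -> float:
        return (self.tme_um * 1e-4) ** 2

    def scales(self) -> dict[str, float]:
        return policy_scales(self.materials)


def desk_preset(**overrides) -> SimulationConfig:
    """A desk-scale preset: 0.5 cm domain, 10^4 cells, 5 training repetitions.

    All rates are per-cell and per-episode, so growth statistics are
    comparable with the full-scale configuration.
    """
    kwargs = dict(
        domain_cm=0.5,
        initial_cells=10_000,
        n_repetitions=5,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def paper_preset(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


_PRESETS = {"desk": desk_preset, "paper": paper_preset}


def load_config(path: str | Path | None = None, preset: str | None = None,
                **overrides) -> SimulationConfig:
    """Build a configuration from a YAML/JSON file, a named preset, or both.

    File sections ``geometry``, ``materials``, ``signaling``, ``drl``, ``nn``
    and ``run`` are flattened onto :class:`SimulationConfig` fields; explicit
    ``overrides`` win over the file, which wins over the preset.
    """
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    file_kwargs: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        raw = raw or {}
        mat_section = raw.pop("materials", None)
        for section in ("geometry", "signaling", "drl", "nn", "run", "policies"):
            file_kwargs.update(raw.pop(section, {}) or {})
        file_kwargs.update(raw)
        if mat_section:
            mats = default_materials()
            for name, vals in mat_section.items():
                mats[name] = MaterialParams(
                    name,
                    vals.get("c_normal", mats[name].c_normal),
                    vals.get("c_max", mats[name].c_max),
                    vals.get("d", mats[name].d),
                    vals.get("rho", mats[name].rho),
                )
            file_kwargs["materials"] = mats
        unknown = set(file_kwargs) - fields
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    file_kwargs.update(overrides)
    if "hidden_layers" in file_kwargs:
        file_kwargs["hidden_layers"] = tuple(file_kwargs["hidden_layers"])
    builder = _PRESETS.get(preset or "paper")
    if builder is None:
        raise ConfigurationError(f"unknown preset {preset!r}; choose desk or paper")
    return builder(**file_kwargs)
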