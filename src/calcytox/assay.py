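"""Mechanistic simulator of the 4-hour calcein-AM cytotoxicity assay.

Target tumor cells are loaded with calcein (heterogeneous loading), then
incubated with NK effector cells. At the endpoint each target is in one of
three states:

* **alive** — retains its calcein apart from a spontaneous leak fraction;
* **killed, necrosis-like** — membrane rupture empties most calcein into the
  supernatant, leaving a dim remnant;
* **killed, apoptotic** — the cell blebs into several small apoptotic bodies
  that retain (up to all of) the calcein instead of releasing it.

Effector cells are never simulated as particles: they are not calcein-loaded
and are therefore invisible in the fluorescence channel.

Killing is modeled as a single end-of-assay Bernoulli event per target; both
assay readouts (supernatant fluorescence and live-cell counting) are endpoint
measurements, so the 4-hour kinetics are collapsed to the final state.

Calcein is conserved exactly: for every simulated well,
``supernatant_calcein + sum(particle.calcein) == total_loaded`` to floating
point round-off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import yaml

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "AssayParams",
    "WellSpec",
    "ParticleState",
    "WellState",
    "load_calcein",
    "lyse_cell",
    "simulate_well",
    "LIVE_CELL",
    "NECROTIC_REMNANT",
    "APOPTOTIC_BODY",
]

LIVE_CELL = "live_cell"
NECROTIC_REMNANT = "necrotic_remnant"
APOPTOTIC_BODY = "apoptotic_body"

ROLES = ("test", "spontaneous", "maximum")

#: Side of the square counting-chamber region over which in-well particle
#: positions are drawn (μm). Provenance only: slide loading re-randomizes
#: positions before imaging (see imaging.sample_field).
CHAMBER_UM = 3000.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise InvalidParameterError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class AssayParams:
    """Biophysical parameters of the simulated calcein assay.

    Parameters
    ----------
    load_mean
        Mean calcein content per loaded cell, arbitrary units (AU).
    load_cv
        Coefficient of variation of loading across cells (lognormal model).
    leak_frac
        Fraction of a live cell's calcein released spontaneously over the
        4-hour assay (same deterministic fraction for every live cell).
    kill_frac_by_et
        Map E:T ratio -> probability that a target is killed by the assay
        endpoint. Ratios absent from the map are rejected, not interpolated.
    apoptotic_frac
        Among killed cells, the fraction dying apoptotically (the rest die
        necrosis-like).
    necrotic_retention
        Fraction of a necrotically killed cell's calcein kept in its remnant.
    apoptotic_retention
        Fraction of an apoptotically killed cell's calcein kept, in total,
        across its apoptotic bodies.
    bodies_per_cell
        Number of apoptotic bodies produced per apoptotic death.
    live_diameter_um, body_diameter_um
        Physical diameters of live cells and apoptotic bodies.
    """

    load_mean: float = 100.0
    load_cv: float = 0.25
    leak_frac: float = 0.15
    kill_frac_by_et: dict = field(
        default_factory=lambda: {2.0: 0.9, 1.0: 0.6, 0.5: 0.35}
    )
    apoptotic_frac: float = 0.3
    necrotic_retention: float = 0.1
    apoptotic_retention: float = 1.0
    bodies_per_cell: int = 20
    live_diameter_um: float = 16.0
    body_diameter_um: float = 4.0

    def __post_init__(self) -> None:
        if self.load_mean <= 0:
            raise InvalidParameterError("load_mean must be > 0")
        if self.load_cv < 0:
            raise InvalidParameterError("load_cv must be >= 0")
        for name in ("leak_frac", "apoptotic_frac", "necrotic_retention",
                     "apoptotic_retention"):
            _check_fraction(name, getattr(self, name))
        self.kill_frac_by_et = {float(k): float(v)
                                for k, v in self.kill_frac_by_et.items()}
        for et, k in self.kill_frac_by_et.items():
            if et <= 0:
                raise InvalidParameterError("E:T ratios must be > 0")
            _check_fraction(f"kill_frac_by_et[{et}]", k)
        if int(self.bodies_per_cell) != self.bodies_per_cell or self.bodies_per_cell < 1:
            raise InvalidParameterError("bodies_per_cell must be an integer >= 1")
        self.bodies_per_cell = int(self.bodies_per_cell)
        if self.live_diameter_um <= 0 or self.body_diameter_um <= 0:
            raise InvalidParameterError("diameters must be > 0")
        if self.body_diameter_um >= self.live_diameter_um:
            raise InvalidParameterError(
                "body_diameter_um must be < live_diameter_um")

    def kill_fraction(self, et_ratio: float) -> float:
        """Kill probability for ``et_ratio``; unknown ratios are an error."""
        for et, k in self.kill_frac_by_et.items():
            if math.isclose(et, float(et_ratio), rel_tol=1e-9, abs_tol=1e-12):
                return k
        raise ConfigurationError(
            f"E:T ratio {et_ratio} not present in kill_frac_by_et "
            f"(known: {sorted(self.kill_frac_by_et)}); ratios are not interpolated"
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        # JSON object keys must be strings; keep YAML consistent with JSON.
        d["kill_frac_by_et"] = {str(k): v for k, v in self.kill_frac_by_et.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AssayParams":
        d = dict(d)
        if "kill_frac_by_et" in d:
            d["kill_frac_by_et"] = {float(k): float(v)
                                    for k, v in d["kill_frac_by_et"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AssayParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "AssayParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "AssayParams":
        return replace(self, **kwargs)


@dataclass
class WellSpec:
    """Design of one well: its role, E:T ratio, target count and seed."""

    role: str
    et_ratio: float = 0.0
    n_targets: int = 10000
    seed: int = 0
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidParameterError(
                f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "test" and self.et_ratio <= 0:
            raise InvalidParameterError("test wells require et_ratio > 0")
        if self.role != "test" and self.et_ratio not in (0, 0.0):
            raise InvalidParameterError("control wells must have et_ratio == 0")
        if self.n_targets < 1:
            raise InvalidParameterError("n_targets must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "WellSpec":
        return cls(**d)


@dataclass
class ParticleState:
    """One fluorescent entity in a well.

    ``position`` is the (x, y) location in the counting chamber in μm; it is
    assigned by :func:`simulate_well` and treated as provenance only (slide
    loading re-randomizes positions before imaging).
    """

    kind: str
    calcein: float
    diameter_um: float
    position: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in (LIVE_CELL, NECROTIC_REMNANT, APOPTOTIC_BODY):
            raise InvalidParameterError(f"unknown particle kind {self.kind!r}")
        if self.calcein < 0:
            raise InvalidParameterError("calcein must be >= 0")
        if self.diameter_um <= 0:
            raise InvalidParameterError("diameter_um must be > 0")


@dataclass
class WellState:
    """Endpoint state of a simulated well."""

    spec: WellSpec
    particles: list
    supernatant_calcein: float
    total_loaded: float

    def count(self, kind: str) -> int:
        return sum(1 for p in self.particles if p.kind == kind)

    @property
    def particle_calcein(self) -> float:
        return float(sum(p.calcein for p in self.particles))

    def conservation_error(self) -> float:
        """Relative calcein conservation error (should be ~1e-16)."""
        if self.total_loaded == 0:
            return 0.0
        return abs(self.supernatant_calcein + self.particle_calcein
                   - self.total_loaded) / self.total_loaded


def load_calcein(n_cells: int, params: AssayParams, seed=None) -> np.ndarray:
    """Draw per-cell calcein loads (AU).

    Loading heterogeneity follows a lognormal with mean ``load_mean`` and
    coefficient of variation ``load_cv`` — strictly positive and right-skewed,
    which matches the divergent loading efficiency seen across cell lines.
    ``load_cv == 0`` degenerates to a constant.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if params.load_mean <= 0:
        raise InvalidParameterError("load_mean must be > 0")
    rng = _as_rng(seed)
    if params.load_cv == 0:
        return np.full(int(n_cells), float(params.load_mean))
    sigma2 = math.log1p(params.load_cv ** 2)
    mu = math.log(params.load_mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=int(n_cells))


def lyse_cell(calcein: float, mode: str, params: AssayParams, seed=None):
    """Lyse one target cell; returns ``(released, fragments)``.

    Necrosis-like death ruptures the membrane: a single dim remnant keeps
    ``necrotic_retention`` of the calcein and the rest enters the supernatant.
    Apoptotic death produces ``bodies_per_cell`` apoptotic bodies jointly
    keeping ``apoptotic_retention`` of the calcein, split across bodies by a
    symmetric (uniform) Dirichlet draw.

    Conservation is exact: ``released + sum(f.calcein for f in fragments)``
    equals ``calcein``.
    """
    if calcein < 0:
        raise InvalidParameterError("calcein must be >= 0")
    rng = _as_rng(seed)
    if mode == "necrotic":
        retained = params.necrotic_retention * calcein
        fragments = [ParticleState(NECROTIC_REMNANT, retained,
                                   params.live_diameter_um)]
        released = calcein - retained
    elif mode == "apoptotic":
        retained = params.apoptotic_retention * calcein
        w = rng.dirichlet(np.ones(params.bodies_per_cell))
        amounts = retained * w
        fragments = [ParticleState(APOPTOTIC_BODY, float(a),
                                   params.body_diameter_um)
                     for a in amounts]
        released = calcein - float(amounts.sum())
    else:
        raise InvalidParameterError(
            f"unknown lysis mode {mode!r} (expected 'necrotic' or 'apoptotic')")
    return released, fragments


def simulate_well(spec: WellSpec, params: AssayParams) -> WellState:
    """Simulate one well to its 4-hour endpoint.

    * ``maximum`` — detergent (Triton X-100) solubilizes every cell: all
      loaded calcein is in the supernatant and no fluorescent particle
      remains.
    * ``spontaneous`` — no effectors: every cell survives and leaks
      ``leak_frac`` of its calcein.
    * ``test`` — each target is killed independently with probability
      ``kill_frac_by_et[et_ratio]``; killed cells die apoptotically with
      probability ``apoptotic_frac`` (else necrosis-like) and are lysed via
      :func:`lyse_cell`; survivors leak like the spontaneous control.
    """
    rng = np.random.default_rng(spec.seed)
    loads = load_calcein(spec.n_targets, params, rng)
    total = float(loads.sum())

    if spec.role == "maximum":
        return WellState(spec=spec, particles=[],
                         supernatant_calcein=total, total_loaded=total)

    particles: list[ParticleState] = []
    supernatant = 0.0

    if spec.role == "spontaneous":
        killed = np.zeros(spec.n_targets, dtype=bool)
    else:
        k = params.kill_fraction(spec.et_ratio)
        killed = rng.random(spec.n_targets) < k

    apoptotic = rng.random(spec.n_targets) < params.apoptotic_frac

    for load, was_killed, is_apop in zip(loads, killed, apoptotic):
        if was_killed:
            mode = "apoptotic" if is_apop else "necrotic"
            released, fragments = lyse_cell(float(load), mode, params, rng)
            supernatant += released
            particles.extend(fragments)
        else:
            leaked = params.leak_frac * float(load)
            supernatant += leaked
            particles.append(ParticleState(LIVE_CELL, float(load) - leaked,
                                           params.live_diameter_um))

    # Exact conservation: recompute supernatant as the complement.
    supernatant = total - float(sum(p.calcein for p in particles))

    if particles:
        xy = rng.uniform(0.0, CHAMBER_UM, size=(len(particles), 2))
        for p, pos in zip(particles, xy):
            p.position = (float(pos[0]), float(pos[1]))

    return WellState(spec=spec, particles=particles,
                     supernatant_calcein=supernatant, total_loaded=total)
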