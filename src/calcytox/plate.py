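"""Plate-level orchestration: simulate -> render -> detect -> gate -> count.

A :class:`PlateConfig` describes one assay plate — test wells at several E:T
ratios in replicate, plus spontaneous (plain media) and maximum (detergent)
release controls — and :func:`run_plate` executes the full pipeline
deterministically from a single master seed. Per-well seeds are derived with
``numpy.random.SeedSequence([master_seed, well_index])`` so wells are
independent yet reproducible.

:func:`analyze_images` is the analysis-only entry point: given externally
produced field images (TIFF) or per-object measurement tables (CSV) and a
plate map identifying well roles, it runs the identical pipeline from the
detection stage onward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assay import AssayParams, WellSpec, WellState, simulate_well, LIVE_CELL
from .cytometry import (DetectionParams, Gate, count_live, derive_gate,
                        detect_objects, read_object_table,
                        write_object_table)
from .errors import ConfigurationError, GatingError
from .imaging import (ImageSpec, acquire_fields, read_field, write_field)
from .readouts import (CountPair, ReleaseTriplet, dynamic_range,
                       percent_lysis_imaging, percent_lysis_release, qc_flag)

__all__ = [
    "PlateConfig",
    "PlateResult",
    "run_plate",
    "analyze_images",
    "run_donor_panel",
    "derive_well_seeds",
]

logger = logging.getLogger("calcytox")

#: Plate-reader fluorescence counts per AU of supernatant calcein. Any
#: common positive constant cancels in the release formula.
RELEASE_FLUOR_PER_AU = 1.0

WELL_COLUMNS = [
    "well_id", "role", "et_ratio", "replicate", "seed",
    "n_targets", "supernatant_fluorescence", "n_particles",
    "n_frames", "n_rendered", "true_live_rendered", "live_count",
    "pct_lysis_release", "pct_lysis_imaging", "qc",
]


def detect_well(fields, detection: DetectionParams) -> pd.DataFrame:
    """Detect objects on every frame of a well and pool the tables.

    Labels are offset per frame so they stay unique within the well.
    """
    tables = []
    offset = 0
    for field_image in fields:
        table = detect_objects(field_image, detection)
        if len(table):
            table = table.assign(label=table["label"] + offset)
            offset = int(table["label"].max())
            tables.append(table)
    if not tables:
        return detect_objects(fields[0], detection)  # empty, right schema
    return pd.concat(tables, ignore_index=True)


@dataclass
class PlateConfig:
    """Full configuration of one simulated assay plate."""

    cell_line_label: str = "K562-like"
    assay_params: AssayParams = field(default_factory=AssayParams)
    image_spec: ImageSpec = field(default_factory=ImageSpec)
    detection_params: DetectionParams = field(default_factory=DetectionParams)
    gate_percentile_q: float = 5.0
    et_ratios: list = field(default_factory=lambda: [2.0, 1.0, 0.5])
    n_test_replicates: int = 3
    n_control_replicates: int = 6
    n_targets_per_well: int = 10000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.et_ratios:
            raise ConfigurationError("et_ratios must be non-empty")
        if self.n_test_replicates < 1 or self.n_control_replicates < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if self.n_targets_per_well < 1:
            raise ConfigurationError("n_targets_per_well must be >= 1")
        # Surface configuration errors before any simulation runs.
        for et in self.et_ratios:
            self.assay_params.kill_fraction(et)

    def wells(self) -> list[WellSpec]:
        """Well specs in plate order: spontaneous, maximum, then tests."""
        specs = []
        for rep in range(self.n_control_replicates):
            specs.append(WellSpec("spontaneous", 0.0, self.n_targets_per_well,
                                  well_id=f"spont_{rep + 1:02d}"))
            specs.append(WellSpec("maximum", 0.0, self.n_targets_per_well,
                                  well_id=f"max_{rep + 1:02d}"))
        for et in self.et_ratios:
            for rep in range(self.n_test_replicates):
                specs.append(WellSpec("test", float(et),
                                      self.n_targets_per_well,
                                      well_id=f"et{et:g}_{rep + 1:02d}"))
        return specs

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cell_line_label": self.cell_line_label,
            "assay_params": self.assay_params.to_dict(),
            "image_spec": self.image_spec.to_dict(),
            "detection_params": self.detection_params.to_dict(),
            "gate_percentile_q": self.gate_percentile_q,
            "et_ratios": list(self.et_ratios),
            "n_test_replicates": self.n_test_replicates,
            "n_control_replicates": self.n_control_replicates,
            "n_targets_per_well": self.n_targets_per_well,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateConfig":
        d = dict(d)
        if "assay_params" in d:
            d["assay_params"] = AssayParams.from_dict(d["assay_params"])
        if "image_spec" in d:
            d["image_spec"] = ImageSpec.from_dict(d["image_spec"])
        if "detection_params" in d:
            d["detection_params"] = DetectionParams.from_dict(
                d["detection_params"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PlateConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kwargs) -> "PlateConfig":
        return replace(self, **kwargs)


@dataclass
class PlateResult:
    """Per-well rows, per-E:T summary, gate and provenance of one plate."""

    wells: pd.DataFrame
    summary: pd.DataFrame
    gate: Gate | None
    spont_pct_of_max: float | None = None
    dynamic_range_pct: float | None = None
    config: PlateConfig | None = None

    def to_long(self) -> pd.DataFrame:
        """Per-well results in long form: one row per (well, method)."""
        rows = []
        for _, r in self.wells.iterrows():
            rows.append((r["well_id"], r["role"], r["et_ratio"], "release",
                         r["pct_lysis_release"]))
            rows.append((r["well_id"], r["role"], r["et_ratio"], "imaging",
                         r["pct_lysis_imaging"]))
        return pd.DataFrame(
            rows, columns=["well_id", "role", "et_ratio", "method", "value"])

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.wells.to_csv(directory / "wells.csv", index=False)
        self.summary.to_csv(directory / "summary.csv", index=False)
        self.to_long().to_csv(directory / "results.csv", index=False)
        if self.gate is not None:
            self.gate.to_json(directory / "gate.json")
        if self.config is not None:
            self.config.to_yaml(directory / "config.yaml")
        return directory


def derive_well_seeds(master_seed: int, well_index: int) -> tuple[int, int]:
    """Deterministic (simulation, imaging) seed pair for one well."""
    state = np.random.SeedSequence(
        [int(master_seed), int(well_index)]).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def _summarize(wells: pd.DataFrame, et_ratios) -> pd.DataFrame:
    rows = []
    tests = wells[wells["role"] == "test"]
    for et in et_ratios:
        sub = tests[tests["et_ratio"] == float(et)]
        rows.append({
            "et_ratio": float(et),
            "n_replicates": len(sub),
            "mean_pct_lysis_release": sub["pct_lysis_release"].mean(),
            "sd_pct_lysis_release": sub["pct_lysis_release"].std(ddof=1),
            "mean_pct_lysis_imaging": sub["pct_lysis_imaging"].mean(),
            "sd_pct_lysis_imaging": sub["pct_lysis_imaging"].std(ddof=1),
        })
    return pd.DataFrame(rows)


def run_plate(config: PlateConfig, output_dir=None,
              write_images: bool = False) -> PlateResult:
    """Run the full simulated assay plate.

    Deterministic for a fixed ``master_seed``. When ``write_images`` is set
    (requires ``output_dir``), every rendered field is written as TIFF with
    its truth CSV, every object table as CSV, alongside the plate map,
    results tables and gate.
    """
    specs = config.wells()
    out = Path(output_dir) if output_dir is not None else None
    if write_images and out is None:
        raise ConfigurationError("write_images requires an output_dir")
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    states: list[WellState] = []
    tables: dict[str, pd.DataFrame] = {}
    true_live: dict[str, int] = {}
    n_rendered: dict[str, int] = {}
    n_frames: dict[str, int] = {}
    plate_map_rows = []

    for i, spec in enumerate(specs):
        sim_seed, img_seed = derive_well_seeds(config.master_seed, i)
        spec.seed = sim_seed
        state = simulate_well(spec, config.assay_params)
        states.append(state)
        row = {"well_id": spec.well_id, "role": spec.role,
               "et_ratio": spec.et_ratio,
               "supernatant_fluorescence":
                   state.supernatant_calcein * RELEASE_FLUOR_PER_AU}
        if spec.role != "maximum":
            rng = np.random.default_rng(img_seed)
            fields = acquire_fields(state, config.image_spec, rng)
            table = detect_well(fields, config.detection_params)
            tables[spec.well_id] = table
            true_live[spec.well_id] = int(sum(
                (fi.truth["kind"] == LIVE_CELL).sum() for fi in fields))
            n_rendered[spec.well_id] = int(sum(len(fi.truth)
                                               for fi in fields))
            n_frames[spec.well_id] = len(fields)
            if write_images:
                names = []
                for j, fi in enumerate(fields):
                    image_path = out / f"{spec.well_id}_f{j}.tiff"
                    write_field(fi, image_path)
                    names.append(image_path.name)
                write_object_table(table, out / f"{spec.well_id}_objects.csv")
                row["image"] = ";".join(names)
        logger.info("well=%s role=%s seed=%d particles=%d rendered=%s",
                    spec.well_id, spec.role, sim_seed, len(state.particles),
                    n_rendered.get(spec.well_id, "-"))
        plate_map_rows.append(row)

    gate = derive_gate(
        [tables[s.well_id] for s in specs if s.role == "spontaneous"],
        q=config.gate_percentile_q,
        min_diameter_um=config.detection_params.min_diameter_um)
    logger.info("gate min_integrated_intensity=%.1f (q=%g)",
                gate.min_integrated_intensity, gate.percentile_q)

    live_counts = {wid: count_live(tbl, gate) for wid, tbl in tables.items()}

    spont_fluor = np.mean([s.supernatant_calcein for s, sp in
                           zip(states, specs) if sp.role == "spontaneous"]
                          ) * RELEASE_FLUOR_PER_AU
    max_fluor = np.mean([s.supernatant_calcein for s, sp in
                         zip(states, specs) if sp.role == "maximum"]
                        ) * RELEASE_FLUOR_PER_AU
    spont_count = np.mean([live_counts[sp.well_id] for sp in specs
                           if sp.role == "spontaneous"])

    rows = []
    rep_counter: dict[tuple, int] = {}
    for spec, state in zip(specs, states):
        key = (spec.role, spec.et_ratio)
        rep_counter[key] = rep_counter.get(key, 0) + 1
        fluor = state.supernatant_calcein * RELEASE_FLUOR_PER_AU
        release_pct = imaging_pct = np.nan
        flags = []
        if spec.role == "test":
            release_pct = percent_lysis_release(
                ReleaseTriplet(fluor, spont_fluor, max_fluor))
            imaging_pct = percent_lysis_imaging(
                CountPair(spont_count, live_counts[spec.well_id]))
            flags = [f for f in (qc_flag(release_pct), qc_flag(imaging_pct))
                     if f]
        rows.append({
            "well_id": spec.well_id,
            "role": spec.role,
            "et_ratio": spec.et_ratio,
            "replicate": rep_counter[key],
            "seed": spec.seed,
            "n_targets": spec.n_targets,
            "supernatant_fluorescence": fluor,
            "n_particles": len(state.particles),
            "n_frames": n_frames.get(spec.well_id, 0),
            "n_rendered": n_rendered.get(spec.well_id, 0),
            "true_live_rendered": true_live.get(spec.well_id, np.nan),
            "live_count": live_counts.get(spec.well_id, np.nan),
            "pct_lysis_release": release_pct,
            "pct_lysis_imaging": imaging_pct,
            "qc": ";".join(flags),
        })
    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    summary = _summarize(wells, config.et_ratios)
    spont_pct, dr_pct = dynamic_range(max_fluor, spont_fluor)

    result = PlateResult(wells=wells, summary=summary, gate=gate,
                         spont_pct_of_max=spont_pct,
                         dynamic_range_pct=dr_pct, config=config)
    if out is not None:
        result.write(out)
        pd.DataFrame(plate_map_rows).to_csv(out / "plate_map.csv",
                                            index=False)
    return result


def analyze_images(plate_map, image_spec: ImageSpec | None = None,
                   detection_params: DetectionParams | None = None,
                   gate_percentile_q: float = 5.0,
                   base_dir=None) -> PlateResult:
    """Analyze externally produced field images or object tables.

    ``plate_map`` is a CSV path or DataFrame with columns ``well_id``,
    ``role``, ``et_ratio`` and either ``image`` (TIFF path) or ``objects``
    (object-table CSV path); an optional ``supernatant_fluorescence`` column
    additionally enables the release readout. Paths are resolved relative to
    ``base_dir`` (defaults to the plate map's directory).

    Unreadable files are reported per well and skipped; missing spontaneous
    wells raise :class:`~calcytox.errors.GatingError`.
    """
    image_spec = image_spec or ImageSpec()
    detection_params = detection_params or DetectionParams()
    if isinstance(plate_map, (str, Path)):
        plate_path = Path(plate_map)
        plate = pd.read_csv(plate_path)
        base = Path(base_dir) if base_dir is not None else plate_path.parent
    else:
        plate = plate_map.copy()
        base = Path(base_dir) if base_dir is not None else Path(".")
    for col in ("well_id", "role", "et_ratio"):
        if col not in plate.columns:
            raise ConfigurationError(f"plate map lacks required column {col!r}")
    if not (plate["role"] == "spontaneous").any():
        raise GatingError(
            "plate map contains no spontaneous wells; the live-cell gate "
            "is derived from spontaneous controls")

    tables: dict[str, pd.DataFrame] = {}
    errors: dict[str, str] = {}
    for _, row in plate.iterrows():
        wid = str(row["well_id"])
        if row["role"] == "maximum":
            continue
        try:
            if "objects" in plate.columns and isinstance(row.get("objects"), str):
                tables[wid] = read_object_table(base / row["objects"])
            elif "image" in plate.columns and isinstance(row.get("image"), str):
                fields = [read_field(base / name, image_spec)
                          for name in row["image"].split(";")]
                tables[wid] = detect_well(fields, detection_params)
            else:
                raise FileNotFoundError("no image or objects entry")
        except Exception as exc:  # per-file error, run continues
            errors[wid] = str(exc)
            logger.error("well %s: %s", wid, exc)

    spont_tables = [tables[str(r["well_id"])]
                    for _, r in plate.iterrows()
                    if r["role"] == "spontaneous"
                    and str(r["well_id"]) in tables]
    if not spont_tables:
        raise GatingError("no readable spontaneous wells in plate map")
    gate = derive_gate(spont_tables, q=gate_percentile_q,
                       min_diameter_um=detection_params.min_diameter_um)
    live_counts = {wid: count_live(tbl, gate) for wid, tbl in tables.items()}
    spont_count = np.mean(
        [live_counts[str(r["well_id"])] for _, r in plate.iterrows()
         if r["role"] == "spontaneous" and str(r["well_id"]) in live_counts])

    have_release = "supernatant_fluorescence" in plate.columns
    if have_release:
        spont_fluor = plate.loc[plate["role"] == "spontaneous",
                                "supernatant_fluorescence"].mean()
        max_rows = plate.loc[plate["role"] == "maximum",
                             "supernatant_fluorescence"]
        max_fluor = max_rows.mean() if len(max_rows) else np.nan
        have_release = np.isfinite(spont_fluor) and np.isfinite(max_fluor)

    rows = []
    rep_counter: dict[tuple, int] = {}
    for _, prow in plate.iterrows():
        wid = str(prow["well_id"])
        role = str(prow["role"])
        et = float(prow["et_ratio"])
        key = (role, et)
        rep_counter[key] = rep_counter.get(key, 0) + 1
        release_pct = imaging_pct = np.nan
        flags = [errors[wid]] if wid in errors else []
        if role == "test" and wid in live_counts:
            imaging_pct = percent_lysis_imaging(
                CountPair(spont_count, live_counts[wid]))
            if have_release and np.isfinite(
                    prow.get("supernatant_fluorescence", np.nan)):
                release_pct = percent_lysis_release(ReleaseTriplet(
                    float(prow["supernatant_fluorescence"]),
                    float(spont_fluor), float(max_fluor)))
            flags += [f for f in (qc_flag(imaging_pct),) if f]
        rows.append({
            "well_id": wid,
            "role": role,
            "et_ratio": et,
            "replicate": rep_counter[key],
            "seed": np.nan,
            "n_targets": np.nan,
            "supernatant_fluorescence":
                prow.get("supernatant_fluorescence", np.nan),
            "n_particles": np.nan,
            "n_frames": np.nan,
            "n_rendered": np.nan,
            "true_live_rendered": np.nan,
            "live_count": live_counts.get(wid, np.nan),
            "pct_lysis_release": release_pct,
            "pct_lysis_imaging": imaging_pct,
            "qc": ";".join(flags),
        })
    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    et_ratios = sorted({float(r["et_ratio"]) for _, r in plate.iterrows()
                        if r["role"] == "test"})
    summary = _summarize(wells, et_ratios)
    spont_pct = dr_pct = None
    if have_release:
        spont_pct, dr_pct = dynamic_range(float(max_fluor),
                                          float(spont_fluor))
    return PlateResult(wells=wells, summary=summary, gate=gate,
                       spont_pct_of_max=spont_pct, dynamic_range_pct=dr_pct)


def run_donor_panel(config: PlateConfig, n_donors: int = 5,
                    et_ratio: float = 1.0,
                    potency_range: tuple = (0.8, 1.2),
                    seed: int = 0) -> pd.DataFrame:
    """Simulate a donor panel and collect paired per-replicate readouts.

    Each simulated donor scales every kill fraction by a potency factor
    drawn uniformly from ``potency_range`` (clipped to 0.98), emulating
    donor-to-donor variability in NK cytolytic activity, then runs a plate
    restricted to ``et_ratio``. Returns one row per (donor, replicate) with
    both percent-lysis values, ready for :func:`~calcytox.readouts.compare_methods`.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for donor in range(n_donors):
        potency = rng.uniform(*potency_range)
        scaled = {et: min(0.98, k * potency)
                  for et, k in config.assay_params.kill_frac_by_et.items()}
        donor_seed = int(np.random.SeedSequence(
            [int(seed), 1000 + donor]).generate_state(1)[0] % 2**31)
        donor_config = config.replace(
            assay_params=config.assay_params.replace(kill_frac_by_et=scaled),
            et_ratios=[et_ratio],
            master_seed=donor_seed,
        )
        result = run_plate(donor_config)
        tests = result.wells[result.wells["role"] == "test"].copy()
        tests.insert(0, "donor", donor + 1)
        frames.append(tests[["donor", "replicate", "et_ratio",
                             "pct_lysis_release", "pct_lysis_imaging"]])
    return pd.concat(frames, ignore_index=True)
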