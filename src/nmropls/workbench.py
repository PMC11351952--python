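"""Configuration, plain-text I/O and the end-to-end analysis driver.

The driver reproduces the whole analysis chain on a simulated cohort:
simulate → reference to lactate → bin → normalize → pairwise OPLS-DA
validation with permutation nulls and KS calls → VIP-based bin selection →
metabolite-region profiling normalized to the control group → per-metabolite
two-way ANOVA with Tukey post-hoc.  All exchange formats are plain text
(delimited tables, JSON reports) and every report embeds the seed and a hash
of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .cohortsim import CohortConfig, default_metabolites, simulate_cohort
from .preproc import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_EXCLUDED,
    DEFAULT_RANGE,
    LACTATE_TARGET,
    LACTATE_WINDOW,
    BinMatrix,
    Spectrum,
    bin_cohort,
    reference_to_lactate,
    total_sum_normalize,
)
from .profiling import heatmap_table, integrate_regions, normalize_to_control, regions_from_specs, select_bins
from .stats import tukey_hsd, two_way_anova
from .validate import CvConfig, run_all_pairwise

__all__ = [
    "RunConfig",
    "SchemaError",
    "write_spectrum",
    "read_spectrum",
    "write_design",
    "read_design",
    "write_bin_matrix",
    "read_bin_matrix",
    "write_report",
    "read_report",
    "run_full_analysis",
]

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


class SchemaError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass
class RunConfig:
    """Everything one full analysis run needs; defaults mirror the standard
    protocol (0.02-ppm bins, 7-fold internal / 8-fold external CV with 100
    repetitions = 800 models, VIP > 1.5, WT/CD control)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    bin_width: float = DEFAULT_BIN_WIDTH
    ppm_range: tuple[float, float] = DEFAULT_RANGE
    excluded: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDED
    reference_target: float = LACTATE_TARGET
    reference_window: tuple[float, float] = LACTATE_WINDOW
    vip_threshold: float = 1.5
    control_group: str = "WT/CD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be >= 0")
        lo, hi = self.ppm_range
        if hi <= lo:
            raise ValueError("empty ppm_range")
        # one global seed fans out to the cohort and the CV machinery
        ss = np.random.SeedSequence(self.seed)
        c1, c2 = ss.spawn(2)
        self.cohort = CohortConfig(
            **{**asdict(self.cohort), "seed": int(c1.generate_state(1)[0] % 2**31)}
        )
        self.cv = CvConfig(
            **{**asdict(self.cv), "seed": int(c2.generate_state(1)[0] % 2**31)}
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = CohortConfig(**{
            **raw.get("cohort", {}),
            **({"groups": tuple(raw["cohort"]["groups"])} if "groups" in raw.get("cohort", {}) else {}),
            **({"ppm_grid": tuple(raw["cohort"]["ppm_grid"])} if "ppm_grid" in raw.get("cohort", {}) else {}),
        })
        cv = CvConfig(**raw.get("cv", {}))
        kw = {k: v for k, v in raw.items() if k not in ("cohort", "cv")}
        for key in ("ppm_range", "reference_window"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "excluded" in kw:
            kw["excluded"] = tuple(tuple(x) for x in kw["excluded"])
        return cls(cohort=cohort, cv=cv, **kw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- file I/O


def write_spectrum(s: Spectrum, path) -> None:
    """Two-column delimited text (ppm, intensity) with a header line."""
    arr = np.column_stack([s.ppm, s.intensity])
    header = "ppm\tintensity"
    np.savetxt(path, arr, fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")


def read_spectrum(path, sample_id: str | None = None) -> Spectrum:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["ppm", "intensity"]:
            raise SchemaError(f"{path}:1: expected header 'ppm\\tintensity', got {header}")
        rows = []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != 2:
                raise SchemaError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as e:
                raise SchemaError(f"{path}:{ln}: {e}") from None
    arr = np.asarray(rows)
    return Spectrum(ppm=arr[:, 0], intensity=arr[:, 1], sample_id=sample_id or path.stem)


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, ["sample_id", "genotype", "diet"], path)
    if "group" not in df.columns:
        df["group"] = df["genotype"] + "/" + df["diet"]
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicate sample ids {dup}")
    return df


def write_bin_matrix(m: BinMatrix, path) -> None:
    """Delimited matrix plus a JSON sidecar with edges, state, exclusions."""
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.sample_ids)
    df.to_csv(path, sep="\t", header=False, float_format=_FLOAT_FMT)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "state": m.state,
        "bin_edges": m.bin_edges.tolist(),
        "excluded_regions": [list(x) for x in m.excluded_regions],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_bin_matrix(path) -> BinMatrix:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"{path}: missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path, sep="\t", header=None, index_col=0, float_precision="round_trip")
    return BinMatrix(
        values=df.to_numpy(dtype=float),
        bin_edges=np.asarray(sidecar["bin_edges"], dtype=float),
        sample_ids=[str(i) for i in df.index],
        state=sidecar["state"],
        excluded_regions=tuple(tuple(x) for x in sidecar["excluded_regions"]),
    )


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=_jsonify))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ------------------------------------------------------------------ driver


def run_full_analysis(cfg: RunConfig, keep_objects: bool = False) -> dict:
    """Simulate a cohort and run the complete analysis chain on it.

    Returns a JSON-serializable report: per-comparison model summaries and
    KS calls, selected bins, the group × metabolite heatmap table (percent
    of control), and per-metabolite two-way ANOVA / Tukey results.  With
    ``keep_objects=True`` the in-memory objects (spectra, matrices, panels,
    validation reports) are attached under ``"objects"``.
    """
    specs = default_metabolites()
    spectra, design, truth = simulate_cohort(cfg.cohort, specs)
    spectra = [
        reference_to_lactate(s, cfg.reference_window, cfg.reference_target)
        for s in spectra
    ]
    raw = bin_cohort(spectra, width=cfg.bin_width, ppm_range=cfg.ppm_range, excluded=cfg.excluded)
    norm = total_sum_normalize(raw)

    reports = run_all_pairwise(norm, design, cfg.cv)
    vips = {label: r.true.vip_mean for label, r in reports.items()}
    selected = select_bins(vips, threshold=cfg.vip_threshold)

    regions = regions_from_specs(specs)
    panel = integrate_regions(norm, regions, design)
    percent = normalize_to_control(panel, cfg.control_group)
    heat = heatmap_table(percent, group_order=cfg.cohort.groups)

    geno = design.set_index("sample_id")["genotype"].reindex(percent.levels.index)
    diet = design.set_index("sample_id")["diet"].reindex(percent.levels.index)
    anova = {}
    tukey = {}
    for met in percent.levels.columns:
        vals = percent.levels[met].to_numpy()
        res = two_way_anova(vals, geno, diet)
        anova[met] = {
            "genotype": {"F": res.genotype.F, "p": res.genotype.p},
            "diet": {"F": res.diet.F, "p": res.diet.p},
            "interaction": {"F": res.interaction.F, "p": res.interaction.p},
        }
        tk = tukey_hsd(vals, percent.groups.to_numpy())
        tukey[met] = tk.table.to_dict(orient="records")

    out = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_samples": len(spectra),
        "n_bins": norm.n_bins,
        "comparisons": {label: r.summary() for label, r in reports.items()},
        "selected_bins": selected.tolist(),
        "n_selected_bins": int(selected.size),
        "heatmap_percent_of_control": {
            g: {m: float(heat.loc[g, m]) for m in heat.columns} for g in heat.index
        },
        "anova": anova,
        "tukey": tukey,
    }
    if keep_objects:
        out["objects"] = {
            "spectra": spectra,
            "design": design,
            "truth": truth,
            "bin_matrix": norm,
            "reports": reports,
            "panel": percent,
        }
    return out
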