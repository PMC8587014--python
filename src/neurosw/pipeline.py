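"""End-to-end orchestration: simulate -> preprocess -> connect -> graph -> stats.

Also hosts the default study configurations (the planted two-cohort
contrast and scaled-down variants for replicate experiments) and the
replicate-level recovery experiment that measures per-band rejection
rates and effect directions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import CANONICAL_BANDS, get_band
from .connectivity import connectivity_stack
from .errors import InvalidSpecError
from .graph import compute_sw_table
from .preprocess import PreprocessConfig, preprocess_recording
from .stats import duncan_posthoc, ks_normality, mixed_anova, report
from .synth import CohortSpec, TopologySpec, simulate_cohorts, write_cohort

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_all",
    "recovery_experiment",
    "default_study_config",
    "scaled_study_config",
    "null_study_config",
    "sw_table_for_cohorts",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def _from_dict(cls, d: dict):
    """Build a dataclass from a plain dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise InvalidSpecError(
            f"unknown key(s) {sorted(unknown)} for {cls.__name__}; "
            f"valid keys: {sorted(names)}"
        )
    kwargs = {}
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    for k, v in d.items():
        if k == "band_topologies":
            v = {name: _from_dict(TopologySpec, dict(t)) for name, t in v.items()}
        elif isinstance(v, dict) and "CohortSpec" in str(types[k]):
            v = _from_dict(CohortSpec, v)
        elif isinstance(v, dict) and "PreprocessConfig" in str(types[k]):
            v = _from_dict(PreprocessConfig, v)
        kwargs[k] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    pd_cohort: CohortSpec
    nold_cohort: CohortSpec
    preprocess: PreprocessConfig = PreprocessConfig()
    measure: str = "lagged_r2"
    alpha: float = 0.05
    duncan_error_stratum: str = "per_band"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_dict(cls, dict(d))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------


def band_lag(band_name: str, fs: float) -> int:
    """Coupling delay of one quarter period of the band center, in samples.

    Keeps the planted within-band phase lag near pi/2, away from 0 and
    pi where lagged coherence vanishes.
    """
    band = get_band(band_name)
    fc = 0.5 * (band.lo + band.hi)
    return max(1, round(fs / (4.0 * fc)))


def _planted_topologies(
    n_nodes: int, fs: float, ordered_theta: bool, degree: int = 4, coupling: float = 0.6
) -> dict[str, TopologySpec]:
    """Band topologies for one cohort of the planted contrast.

    The contrast mirrors the qualitative group difference under study:
    the PD-like cohort gets an ordered (lattice) theta topology and a
    random alpha2 topology; the control-like cohort the reverse.  The
    remaining five bands carry a small-world baseline with identical
    parameters in both cohorts.
    """

    def topo(model: str, band_name: str) -> TopologySpec:
        return TopologySpec(
            n_nodes=n_nodes,
            model=model,
            degree=degree,
            coupling_strength=coupling,
            coupling_lag=band_lag(band_name, fs),
        )

    base = {
        name: dataclasses.replace(topo("smallworld", name), rewiring_prob=0.2)
        for name in ("delta", "alpha1", "beta1", "beta2", "gamma")
    }
    base["theta"] = topo("lattice" if ordered_theta else "random", "theta")
    base["alpha2"] = topo("random" if ordered_theta else "lattice", "alpha2")
    return base


def default_study_config(seed: int = 0) -> PipelineConfig:
    """Full-scale study: 13+13 subjects, 84 ROIs, 6 min at 256 Hz."""
    common = dict(n_subjects=13, duration_s=360.0, fs=256.0, n_nodes=84, noise_sd=1.0)
    return PipelineConfig(
        pd_cohort=CohortSpec(
            band_topologies=_planted_topologies(84, 256.0, ordered_theta=True),
            seed=seed * 2 + 1,
            **common,
        ),
        nold_cohort=CohortSpec(
            band_topologies=_planted_topologies(84, 256.0, ordered_theta=False),
            seed=seed * 2 + 2,
            **common,
        ),
    )


def scaled_study_config(seed: int = 0, n_subjects: int = 13) -> PipelineConfig:
    """Reduced problem size for replicate experiments: 40 ROIs, 64 s at 128 Hz."""
    common = dict(
        n_subjects=n_subjects, duration_s=64.0, fs=128.0, n_nodes=40, noise_sd=1.0
    )
    pre = PreprocessConfig(min_minutes=0.0)
    return PipelineConfig(
        pd_cohort=CohortSpec(
            band_topologies=_planted_topologies(40, 128.0, ordered_theta=True),
            seed=seed * 2 + 1,
            **common,
        ),
        nold_cohort=CohortSpec(
            band_topologies=_planted_topologies(40, 128.0, ordered_theta=False),
            seed=seed * 2 + 2,
            **common,
        ),
        preprocess=pre,
    )


def null_study_config(seed: int = 0, n_subjects: int = 13) -> PipelineConfig:
    """Two identical cohorts of uncoupled noise (small, for size studies)."""
    common = dict(
        n_subjects=n_subjects,
        duration_s=24.0,
        fs=128.0,
        n_nodes=8,
        noise_sd=1.0,
        band_topologies={},
    )
    pre = PreprocessConfig(min_minutes=0.0)
    return PipelineConfig(
        pd_cohort=CohortSpec(seed=seed * 2 + 1, **common),
        nold_cohort=CohortSpec(seed=seed * 2 + 2, **common),
        preprocess=pre,
    )


# --------------------------------------------------------------------------
# execution
# --------------------------------------------------------------------------


@dataclass
class PipelineResult:
    sw_table: pd.DataFrame
    anova: object
    duncan: pd.DataFrame
    normality: pd.DataFrame
    normality_pass: bool
    summary: pd.DataFrame
    rejection_log: pd.DataFrame


def sw_table_for_cohorts(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate both cohorts and run them through preprocessing,
    connectivity and graph analysis.  Returns (sw_table, rejection_log)."""
    recs = simulate_cohorts(config.pd_cohort, config.nold_cohort)
    matrices = {}
    logs = []
    for rec in recs:
        clean, log = preprocess_recording(rec, config.preprocess)
        logs.append(log)
        matrices[(clean.subject_id, clean.group)] = connectivity_stack(
            clean, CANONICAL_BANDS, measure=config.measure
        )
    sw = compute_sw_table(matrices)
    return sw, pd.concat(logs, ignore_index=True)


def run_all(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    write_timeseries: bool = False,
) -> PipelineResult:
    """Execute the full pipeline and (optionally) write the artifact tree.

    Identical config -> identical numeric outputs: every random draw is
    derived from the cohort seeds.
    """
    sw, rej_log = sw_table_for_cohorts(config)
    normality, norm_pass = ks_normality(sw, alpha=config.alpha)
    anova = mixed_anova(sw)
    duncan = duncan_posthoc(
        sw, anova, alpha=config.alpha, error_stratum=config.duncan_error_stratum
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if write_timeseries:
            write_cohort(
                simulate_cohorts(config.pd_cohort, config.nold_cohort),
                out_dir / "timeseries",
            )
        sw.to_csv(out_dir / "sw_table.csv", index=False)
        rej_log.to_csv(out_dir / "rejection_log.csv", index=False)
        normality.to_csv(out_dir / "normality.csv", index=False)
        duncan.to_csv(out_dir / "duncan.csv", index=False)
        (out_dir / "anova.json").write_text(
            json.dumps(
                {name: rep.to_dict() for name, rep in anova.reports.items()},
                indent=1,
            )
        )
        (out_dir / "provenance.json").write_text(
            json.dumps(
                {
                    "config_hash": config.config_hash(),
                    "seeds": {
                        "pd": config.pd_cohort.seed,
                        "nold": config.nold_cohort.seed,
                    },
                    "neurosw_version": __version__,
                    "numpy_version": np.__version__,
                },
                indent=1,
            )
        )
        summary, fig = report(sw, anova, duncan, out_dir=out_dir)
        import matplotlib.pyplot as plt

        plt.close(fig)
    else:
        summary, fig = report(sw, anova, duncan)
        import matplotlib.pyplot as plt

        plt.close(fig)

    return PipelineResult(
        sw_table=sw,
        anova=anova,
        duncan=duncan,
        normality=normality,
        normality_pass=norm_pass,
        summary=summary,
        rejection_log=rej_log,
    )


def _replicate_config(config: PipelineConfig, seed: int) -> PipelineConfig:
    return dataclasses.replace(
        config,
        pd_cohort=dataclasses.replace(config.pd_cohort, seed=seed * 2 + 1),
        nold_cohort=dataclasses.replace(config.nold_cohort, seed=seed * 2 + 2),
    )


def recovery_experiment(
    config: PipelineConfig,
    n_replicates: int,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Replicate the full pipeline and summarize per-band decisions.

    Each replicate re-simulates both cohorts under fresh derived seeds,
    runs the pipeline, and records per band the PD - Nold mean SW
    difference and the Duncan decision, plus the GG-corrected
    interaction p.  Returns one row per (replicate, band).
    """
    rows = []
    reps = range(n_replicates)
    if progress:
        from tqdm import tqdm

        reps = tqdm(reps)
    for r in reps:
        # keep derived seeds well below 2**31
        rep_seed = (base_seed * 20011 + r) % 1_000_000_007
        cfg = _replicate_config(config, rep_seed)
        sw, _ = sw_table_for_cohorts(cfg)
        anova = mixed_anova(sw)
        duncan = duncan_posthoc(
            sw, anova, alpha=cfg.alpha, error_stratum=cfg.duncan_error_stratum
        )
        p_int = anova["Group x Band"].p_gg
        for _, row in duncan.iterrows():
            rows.append(
                {
                    "replicate": r,
                    "band": row["band"],
                    "difference": row["difference"],
                    "significant": row["significant"],
                    "interaction_p_gg": p_int,
                }
            )
    return pd.DataFrame(rows)
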