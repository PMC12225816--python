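"""Inter-individual variability simulation for segment parameters.

Individualized parameter sets are drawn around a reference record under the
stated correlation structure: linear dimensions are normally distributed and
positively correlated (default: perfectly, via one shared scale factor);
Tb.Th and Tb.Sp are lognormal with a negative rank correlation (default -1,
through a Gaussian copula); cortical thickness is an independent normal
truncated at zero.  BV/TV, when allowed to vary, is drawn uniformly in a
per-segment admissible band.  Correlation magnitudes are configurable because
only their signs are anatomically established.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
import numpy as np

from .db import SegmentRecord
from . import geometry

_MAX_RESAMPLE = 200


@dataclass(frozen=True)
class VariabilityConfig:
    """Cohort-variability settings (CVs in percent, rank correlations in [-1, 1])."""

    cv_dims: float = 0.0
    cv_ct_th: float = 0.0
    cv_tb_th: float = 0.0
    cv_tb_sp: float = 0.0
    dims_rank_corr: float = 1.0
    tbth_tbsp_rank_corr: float = -1.0
    bvtv_range_rel: float = 0.0  # half-width of the admissible BV/TV band, relative
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_dims", "cv_ct_th", "cv_tb_th", "cv_tb_sp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dims_rank_corr", "tbth_tbsp_rank_corr"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.bvtv_range_rel < 1.0:
            raise ValueError("bvtv_range_rel must be in [0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "VariabilityConfig":
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "VariabilityConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _gauss_corr(rank_corr: float) -> float:
    """Pearson correlation of the Gaussian copula giving a Spearman rank correlation."""
    return 2.0 * math.sin(math.pi * rank_corr / 6.0)


def _lognormal_from_mean_cv(mean: float, cv: float, z: float) -> float:
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return math.exp(mu + math.sqrt(sigma2) * z)


class SamplingError(RuntimeError):
    """Resampling failed to produce a record satisfying its invariants."""


def sample_individual(
    record: SegmentRecord,
    cfg: VariabilityConfig,
    rng: np.random.Generator,
) -> SegmentRecord:
    """One individualized copy of ``record`` under the variability model."""
    for _ in range(_MAX_RESAMPLE):
        candidate = _draw(record, cfg, rng)
        if candidate is not None:
            return candidate
    raise SamplingError(f"could not draw a valid individual for {record.key} in {_MAX_RESAMPLE} tries")


def _draw(record: SegmentRecord, cfg: VariabilityConfig, rng: np.random.Generator) -> SegmentRecord | None:
    dims = {k: getattr(record, k) for k in ("h", "a", "b", "c", "d") if getattr(record, k) is not None}
    cv = cfg.cv_dims / 100.0
    if cv > 0:
        rho = _gauss_corr(cfg.dims_rank_corr)
        shared = rng.standard_normal()
        new_dims = {}
        for k, v in dims.items():
            z = rho * shared + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal()
            f = 1.0 + cv * z
            if f <= 0:
                return None
            new_dims[k] = v * f
    else:
        new_dims = dict(dims)

    cv_th = cfg.cv_tb_th / 100.0
    cv_sp = cfg.cv_tb_sp / 100.0
    if cv_th > 0 or cv_sp > 0:
        rho = _gauss_corr(cfg.tbth_tbsp_rank_corr)
        z1 = rng.standard_normal()
        z2 = rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal()
        tb_th = _lognormal_from_mean_cv(record.tb_th, cv_th, z1) if cv_th > 0 else record.tb_th
        tb_sp = _lognormal_from_mean_cv(record.tb_sp, cv_sp, z2) if cv_sp > 0 else record.tb_sp
    else:
        tb_th, tb_sp = record.tb_th, record.tb_sp

    cv_ct = cfg.cv_ct_th / 100.0
    if cv_ct > 0 and record.cortical:
        f = 1.0 + cv_ct * rng.standard_normal()
        if f <= 0:
            return None  # truncation at zero via resampling
        cortical = tuple((face, t * f) for face, t in record.cortical)
    else:
        cortical = record.cortical

    if cfg.bvtv_range_rel > 0:
        lo = record.bvtv * (1.0 - cfg.bvtv_range_rel)
        hi = min(record.bvtv * (1.0 + cfg.bvtv_range_rel), 0.999)
        bvtv = float(rng.uniform(lo, hi))
    else:
        bvtv = record.bvtv

    candidate = replace(
        record,
        h=new_dims.get("h"),
        a=new_dims.get("a"),
        b=new_dims.get("b"),
        c=new_dims.get("c"),
        d=new_dims.get("d"),
        cortical=cortical,
        bvtv=bvtv,
        tb_th=tb_th,
        tb_sp=tb_sp,
    )
    try:
        spec = candidate.shape_spec()
        geometry.spongiosa_volume(spec, candidate.cortical_map())
    except (geometry.ShapeError, geometry.CorticalError):
        return None
    return candidate


def sample_cohort(record: SegmentRecord, cfg: VariabilityConfig) -> list[SegmentRecord]:
    rng = np.random.default_rng(cfg.seed)
    return [sample_individual(record, cfg, rng) for _ in range(cfg.n)]


def cohort_media_cv(record: SegmentRecord, cfg: VariabilityConfig) -> dict:
    """Empirical CVs (%) of TBV/CBV/BMV over a simulated cohort.

    Media volumes are evaluated on the analytic fast path (closed-form shape
    and shell volumes with the drawn BV/TV), so cohorts of thousands cost
    milliseconds.  Monte Carlo standard errors use the large-sample
    approximation SE(CV) ~= CV * sqrt(1/(2(n-1))).
    """
    from .aggregation import segment_media_volumes  # local import to avoid a cycle

    draws = sample_cohort(record, cfg)
    tbv = np.empty(len(draws))
    cbv = np.empty(len(draws))
    bmv = np.empty(len(draws))
    for i, rec in enumerate(draws):
        mv = segment_media_volumes(rec, mode="analytic")
        tbv[i], cbv[i], bmv[i] = mv.tbv, mv.cbv, mv.bmv

    def cv_of(x: np.ndarray) -> float:
        m = x.mean()
        if m <= 0:
            return 0.0
        cv = float(x.std(ddof=1) / m * 100.0)
        return cv if cv > 1e-9 else 0.0  # identical draws leave only float noise

    n = len(draws)
    se_factor = math.sqrt(1.0 / (2.0 * max(n - 1, 1)))
    out = {}
    for name, arr in (("tbv", tbv), ("cbv", cbv), ("bmv", bmv)):
        c = cv_of(arr) if n > 1 else 0.0
        out[f"cv_{name}_percent"] = c
        out[f"cv_{name}_se"] = c * se_factor
        out[f"mean_{name}_cm3"] = float(arr.mean())
    out["n"] = n
    return out
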