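"""Segment, site and skeleton level summaries.

Media volumes (trabecular bone TBV, cortical bone CBV, bone marrow BMV) come
from the analytic closed forms (total shape volume minus the eroded interior
for the cortex; BV/TV splits the spongiosa) or from voxel counts; truncated
segments are scaled to the whole structure by k_s and multiplied by the
segment count n_s.  Active-marrow (AM) weighted "effective" parameters
average the dose-forming quantities the way skeleton doses are averaged:
sites weighted by AM fraction, segments within a site (or AM site group) by
their marrow volume share.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import geometry
from .db import Database, SegmentRecord, AGE_GROUPS

MM3_PER_CM3 = 1000.0


@dataclass(frozen=True)
class MediaVolumes:
    """TBV/CBV/BMV in cm^3 with the corrections that produced them."""

    tbv: float
    cbv: float
    bmv: float
    level: str = "segment"
    n_s: int = 1
    k_s: float = 1.0

    @property
    def spongiosa(self) -> float:
        return self.tbv + self.bmv

    @property
    def total(self) -> float:
        return self.tbv + self.cbv + self.bmv

    def __add__(self, other: "MediaVolumes") -> "MediaVolumes":
        return MediaVolumes(self.tbv + other.tbv, self.cbv + other.cbv, self.bmv + other.bmv, level="sum")


@dataclass(frozen=True)
class EffectiveParams:
    """AM-weighted skeletal averages of the dose-forming parameters."""

    age_group: str
    sex: str
    spongiosa_volume_cm3: float
    bvtv: float
    ct_th_mm: float


@dataclass
class SkeletonSummary:
    age_group: str
    sex: str
    total: MediaVolumes
    by_site: dict[str, MediaVolumes]
    bone_mass_g: float
    marrow_mass_g: float
    mode: str = "analytic"


def segment_media_volumes(
    record: SegmentRecord,
    mode: str = "analytic",
    voxel_size: float | None = None,
    apply_corrections: bool = True,
) -> MediaVolumes:
    """Media volumes of one segment (cm^3), corrected by k_s and n_s.

    ``analytic`` uses closed-form shape and shell volumes; ``voxel``
    rasterizes the segment, applies the cortical shell and counts voxels.
    Both split the spongiosa by the record's BV/TV, so they agree within
    the rasterization error of the geometry.
    """
    spec = record.shape_spec()
    cortical = record.cortical_map()
    if mode == "analytic":
        total = spec.volume()
        spong = geometry.spongiosa_volume(spec, cortical)
    elif mode == "voxel":
        if voxel_size is None:
            voxel_size = geometry.default_voxel_size(record.tb_th)
        ph = geometry.voxelize_shape(spec, voxel_size)
        ph = geometry.apply_cortical_shell(ph, spec, cortical)
        mv = ph.media_volumes_mm3()
        total = mv["total"]
        spong = mv["marrow"] + mv["trabecular"]
    else:
        raise ValueError(f"mode must be 'analytic' or 'voxel', got {mode!r}")
    cbv = total - spong
    tbv = record.bvtv * spong
    bmv = spong - tbv
    scale = (record.k_s * record.n_s if apply_corrections else 1.0) / MM3_PER_CM3
    return MediaVolumes(
        tbv * scale,
        cbv * scale,
        bmv * scale,
        level="segment",
        n_s=record.n_s if apply_corrections else 1,
        k_s=record.k_s if apply_corrections else 1.0,
    )


def skeleton_totals(database: Database, age_group: str, sex: str = "any", mode: str = "analytic") -> SkeletonSummary:
    """Corrected media volumes summed over all segments of one phantom, with masses."""
    model = database.skeleton(age_group, sex)
    by_site: dict[str, MediaVolumes] = {}
    for rec in model.records:
        mv = segment_media_volumes(rec, mode=mode)
        site = rec.am_site()
        by_site[site] = by_site.get(site, MediaVolumes(0, 0, 0, level="site")) + mv
    total = MediaVolumes(0, 0, 0, level="skeleton")
    for mv in by_site.values():
        total = total + mv
    bone_mass = (total.tbv + total.cbv) * model.bone_density
    marrow_mass = total.bmv * model.marrow_density
    return SkeletonSummary(age_group, sex, total, by_site, bone_mass, marrow_mass, mode)


def _segment_ct_th(record: SegmentRecord) -> float:
    """Area-weighted mean cortical thickness over the covered faces (0 if none)."""
    if not record.cortical:
        return 0.0
    spec = record.shape_spec()
    num = den = 0.0
    for face, t in record.cortical:
        area = spec.face_area(face)
        num += t * area
        den += area
    return num / den if den > 0 else 0.0


def effective_parameters(database: Database, age_group: str, sex: str = "any") -> EffectiveParams:
    """AM-weighted effective spongiosa volume, BV/TV and Ct.Th for one phantom.

    Site weights are the AM fractions; inside a site (or a grouped AM cell,
    such as the adult clavicle+scapula+ribs entry) segments are weighted by
    their corrected marrow-volume share, mirroring the assumption that AM is
    uniformly distributed in the marrow of a site.
    """
    model = database.skeleton(age_group, sex)
    by_group: dict[tuple[str, ...], list[tuple[SegmentRecord, MediaVolumes]]] = {}
    for rec in model.records:
        frac, group = model.am.lookup(rec.am_site())  # raises if a site lacks AM
        by_group.setdefault(group, []).append((rec, segment_media_volumes(rec)))

    group_fracs = dict(model.am.entries)
    eff_spong = eff_bvtv = eff_ct = 0.0
    weight_sum = 0.0
    for group, members in by_group.items():
        w_site = group_fracs[group] / 100.0
        bmv_total = sum(mv.bmv for _, mv in members)
        if bmv_total <= 0:
            continue
        for rec, mv in members:
            w = w_site * mv.bmv / bmv_total
            # per-segment spongiosa volume of ONE copy (dose formation happens
            # in a single segment; corrections only set the weights)
            spong_one = (mv.tbv + mv.bmv) / (rec.n_s * rec.k_s)
            eff_spong += w * spong_one
            eff_bvtv += w * rec.bvtv
            eff_ct += w * _segment_ct_th(rec)
            weight_sum += w
    return EffectiveParams(
        age_group=age_group,
        sex=sex,
        spongiosa_volume_cm3=eff_spong / weight_sum,
        bvtv=eff_bvtv / weight_sum,
        ct_th_mm=eff_ct / weight_sum,
    )


#: anatomical multiplicities of the parts of one lumbar vertebra
_LUMBAR_PARTS = {
    "body": (("lbody", "lumbarvertebrabody"), 1),
    "spinous": (("lspinous",), 1),
    "transverse": (("ltransverse",), 2),
    "superior": (("lsuperior",), 2),
    "lamina": (("llamina",), 2),
}


def vertebral_body_fraction(database: Database, age_group: str, sex: str = "any") -> float:
    """Volume share of the vertebral body within one whole lumbar vertebra.

    Uses analytic segment volumes and the anatomical part multiplicities
    (1 body, 1 spinous, 2 transverse, 2 superior, 2 lamina+inferior); ages
    whose phantoms model fewer process types use the parts present.
    """
    model = database.skeleton(age_group, sex)
    volumes: dict[str, float] = {}
    for rec in model.records:
        if rec.site_norm != "vertebra":
            continue
        seg = rec.segment_norm
        for part, (prefixes, mult) in _LUMBAR_PARTS.items():
            if any(seg.startswith(p) for p in prefixes):
                volumes[part] = volumes.get(part, 0.0) + mult * rec.shape_spec().volume()
    if "body" not in volumes:
        raise ValueError(f"no lumbar body segment in the {age_group}/{sex} phantom")
    total = sum(volumes.values())
    return volumes["body"] / total


def effective_bvtv_by_age(database: Database, sex: str = "male") -> dict[str, float]:
    """Effective BV/TV across the age series (sex applies to the sexed ages)."""
    out = {}
    for age in AGE_GROUPS:
        s = sex if age in ("15y", "adult") else "any"
        out[age] = effective_parameters(database, age, s).bvtv
    return out
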