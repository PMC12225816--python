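"""Curated database of bone-segment parameters for eight reference phantoms.

The database ships the segment parameter tables for six reference ages
(newborn, 1, 5, 10, 15 years and adult; the two oldest ages sex-specific),
the age-dependent distribution of active marrow (AM) over skeletal sites,
elemental compositions and media densities.  It can be loaded in ``raw`` mode
(the tables exactly as printed, including evident typos) or ``curated`` mode
(every deviation from print carried by an explicit curation entry).
"""

from __future__ import annotations

import csv
import fnmatch
import io
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

from . import geometry

AGE_GROUPS = ("newborn", "1y", "5y", "10y", "15y", "adult")
SEXED_AGES = ("15y", "adult")
SHAPE_CODES = {"b": "box", "c": "cylinder", "dc": "deformed_cylinder", "p": "prism", "e": "ellipsoid", "t": "tube"}
SHAPE_LETTERS = {v: k for k, v in SHAPE_CODES.items()}

#: the eight reference phantoms as (age_group, sex) pairs
PHANTOMS = (
    ("newborn", "any"),
    ("1y", "any"),
    ("5y", "any"),
    ("10y", "any"),
    ("15y", "male"),
    ("15y", "female"),
    ("adult", "male"),
    ("adult", "female"),
)

#: AM-table site groups that map onto segment-table sites
VERTEBRA_SITES = ("Cervical vertebrae", "Thoracic vertebrae", "Lumbar vertebrae")


class DatabaseError(RuntimeError):
    """Malformed embedded resource or unresolvable query."""


class NoActiveMarrowError(LookupError):
    """The site holds no active marrow at the requested age (a '-' cell)."""


def normalize_name(name: str) -> str:
    """Case/punctuation-insensitive canonical form of a site or segment name."""
    return re.sub(r"[^a-z0-9]", "", name.lower())


@dataclass(frozen=True)
class SegmentRecord:
    """One bone-segment phantom parameter set (lengths in mm)."""

    table_id: str
    age_group: str
    sex: str
    site: str
    segment: str
    shape: str  # geometry kind
    h: float | None
    a: float | None
    b: float | None
    c: float | None
    d: float | None
    cortical: tuple[tuple[str, float], ...]
    bvtv: float
    tb_th: float
    sigma_tb_th: float
    tb_sp: float
    sigma_tb_sp: float
    n_s: int = 1
    k_s: float = 1.0
    sex_distinct: bool = False

    @property
    def key(self) -> str:
        sex = "" if self.sex == "any" else f"/{self.sex}"
        return f"{self.age_group}{sex}/{self.site}/{self.segment}"

    @property
    def truncated(self) -> bool:
        return self.k_s > 1.0

    @property
    def site_norm(self) -> str:
        return normalize_name(self.site)

    @property
    def segment_norm(self) -> str:
        return normalize_name(self.segment)

    def shape_spec(self) -> geometry.ShapeSpec:
        kw = {}
        if self.shape == "deformed_cylinder":
            kw = {"c": self.c, "d": self.d}
        return geometry.ShapeSpec(self.shape, self.h, self.a, self.b, **kw)

    def cortical_map(self) -> dict[str, float]:
        return dict(self.cortical)

    def identity_tuple(self) -> tuple:
        """Everything that defines the segment except its sex, for shared-row detection."""
        return (
            self.age_group,
            self.site_norm,
            self.segment_norm,
            self.shape,
            self.h,
            self.a,
            self.b,
            self.c,
            self.d,
            tuple(sorted(self.cortical)),
            self.bvtv,
            self.tb_th,
            self.sigma_tb_th,
            self.tb_sp,
            self.sigma_tb_sp,
        )

    def am_site(self) -> str:
        """The AM-distribution site this segment belongs to."""
        if self.site_norm == "vertebra":
            first = self.segment_norm[0]
            if first == "c":
                return "Cervical vertebrae"
            if first == "t":
                return "Thoracic vertebrae"
            if first == "l":
                return "Lumbar vertebrae"
            raise DatabaseError(f"cannot classify vertebra segment {self.segment!r}")
        return self.site


@dataclass(frozen=True)
class AMDistribution:
    """Active-marrow fractions (%) by site group for one phantom."""

    age_group: str
    sex: str
    entries: tuple[tuple[tuple[str, ...], float], ...]

    def total(self) -> float:
        return sum(f for _, f in self.entries)

    def lookup(self, site: str) -> tuple[float, tuple[str, ...]]:
        """Fraction and group membership for a site; raises NoActiveMarrowError."""
        norm = normalize_name(site)
        alias = {"radiusandulnae": "radiusandulna", "tibiaandfibula": "tibiaandfibula"}
        norm = alias.get(norm, norm)
        for sites, frac in self.entries:
            if any(normalize_name(s) == norm for s in sites):
                return frac, sites
        raise NoActiveMarrowError(f"no active marrow for site {site!r} in the {self.age_group} {self.sex} phantom")


@dataclass(frozen=True)
class CurationEntry:
    table_id: str
    age_group: str
    sex: str
    site: str
    segment: str
    field: str
    printed: str
    curated: str
    justification: str


@dataclass(frozen=True)
class SkeletonModel:
    """All segment records plus whole-skeleton parameters for one phantom."""

    age_group: str
    sex: str
    records: tuple[SegmentRecord, ...]
    am: AMDistribution
    bone_density: float
    marrow_density: float
    composition: dict[str, dict[str, float]]


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append(CheckResult(name, bool(passed), detail))

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            lines.append(f"[{status}] {c.name}" + (f": {c.detail}" if c.detail else ""))
        return "\n".join(lines)


# -- loading ---------------------------------------------------------------


def _read_resource(name: str) -> str:
    return resources.files("skelvox.data").joinpath(name).read_text(encoding="utf-8")


def _parse_cortical(text: str) -> tuple[tuple[str, float], ...]:
    text = text.strip()
    if not text:
        return ()
    pairs = []
    for token in text.split("+"):
        face, _, thick = token.partition(":")
        pairs.append((face.strip(), float(thick)))
    return tuple(pairs)


def _format_cortical(pairs: Iterable[tuple[str, float]]) -> str:
    return "+".join(f"{f}:{t:g}" for f, t in pairs)


def _float_or_none(text: str) -> float | None:
    text = text.strip()
    return float(text) if text else None


def load_curations() -> tuple[CurationEntry, ...]:
    reader = csv.DictReader(io.StringIO(_read_resource("curations.csv")))
    return tuple(
        CurationEntry(
            row["table_id"], row["age_group"], row["sex"], row["site"], row["segment"],
            row["field"], row["printed"], row["curated"], row["justification"],
        )
        for row in reader
    )


def _apply_curation(rec: SegmentRecord, entry: CurationEntry) -> SegmentRecord:
    f = entry.field
    if f == "sex_distinct":
        return replace(rec, sex_distinct=True)
    if f in ("h", "a", "b", "c", "d"):
        return replace(rec, **{f: _float_or_none(entry.curated)})
    if f == "shape":
        return replace(rec, shape=SHAPE_CODES[entry.curated])
    if f in ("site", "segment"):
        return replace(rec, **{f: entry.curated})
    if f == "cortical":
        return replace(rec, cortical=_parse_cortical(entry.curated))
    raise DatabaseError(f"unknown curation field {f!r}")


def _curation_matches(rec: SegmentRecord, entry: CurationEntry) -> bool:
    if entry.age_group != rec.age_group:
        return False
    if entry.sex != "any" and entry.sex != rec.sex:
        return False
    return (
        normalize_name(entry.site) == rec.site_norm
        and normalize_name(entry.segment) == rec.segment_norm
    )


@dataclass
class MultiplicityRule:
    age_group: str
    site: str
    pattern: str
    n_s: int
    k_s: float
    basis: str


def load_multiplicity_rules() -> tuple[MultiplicityRule, ...]:
    rules = []
    for line in _read_resource("multiplicity.tsv").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("age_group\t"):
            continue
        age, site, pattern, n_s, k_s, basis = line.split("\t")
        rules.append(MultiplicityRule(age, normalize_name(site), pattern, int(n_s), float(k_s), basis))
    return tuple(rules)


def resolve_multiplicity(
    rec: SegmentRecord,
    rules: Iterable[MultiplicityRule],
    overrides: dict[str, tuple[int, float]] | None = None,
) -> tuple[int, float]:
    """(n_s, k_s) for a record: overrides by record key first, then the rule table."""
    if overrides and rec.key in overrides:
        return overrides[rec.key]
    for rule in rules:
        if rule.age_group not in ("*", rec.age_group):
            continue
        if rule.site != rec.site_norm:
            continue
        if fnmatch.fnmatchcase(rec.segment_norm, rule.pattern):
            return rule.n_s, rule.k_s
    return 1, 1.0


class Database:
    """The full segment database in one mode, with query operations."""

    def __init__(
        self,
        mode: str,
        records: tuple[SegmentRecord, ...],
        am: dict[tuple[str, str], AMDistribution],
        densities: dict[str, tuple[float, float]],
        composition: dict[str, dict[str, float]],
        curations: tuple[CurationEntry, ...],
    ):
        self.mode = mode
        self.records = records
        self._am = am
        self._densities = densities
        self.composition = composition
        self.curations = curations

    # -- queries -----------------------------------------------------------

    def skeleton(self, age_group: str, sex: str = "any") -> SkeletonModel:
        if age_group in SEXED_AGES and sex == "any":
            raise DatabaseError(f"{age_group} phantoms are sex-specific; pass sex='male' or 'female'")
        if age_group not in AGE_GROUPS:
            raise DatabaseError(f"unknown age group {age_group!r}; expected one of {AGE_GROUPS}")
        recs = tuple(r for r in self.records if r.age_group == age_group and r.sex in ("any", sex))
        dens = self._densities[age_group]
        return SkeletonModel(
            age_group=age_group,
            sex=sex,
            records=recs,
            am=self.am_distribution(age_group, sex),
            bone_density=dens[0],
            marrow_density=dens[1],
            composition=self.composition,
        )

    def am_distribution(self, age_group: str, sex: str = "any") -> AMDistribution:
        for (age, s), dist in self._am.items():
            if age == age_group and s in ("any", sex):
                return AMDistribution(age_group, sex, dist.entries)
        raise DatabaseError(f"no AM distribution for {age_group}/{sex}")

    def am_fraction(self, age_group: str, sex: str, site: str) -> tuple[float, tuple[str, ...]]:
        """AM fraction (%) of a site; the second element is the printed site group."""
        return self.am_distribution(age_group, sex).lookup(site)

    def densities(self, age_group: str) -> tuple[float, float]:
        """(bone, marrow) density in g/cm^3."""
        return self._densities[age_group]

    def find(self, key: str) -> SegmentRecord:
        """Resolve 'age[/sex]/site/segment' (case/punctuation-insensitive parts)."""
        hits = self.search(key)
        if not hits:
            raise DatabaseError(f"no segment matches {key!r}")
        if len(hits) > 1:
            raise DatabaseError(
                f"ambiguous key {key!r}; candidates: " + ", ".join(r.key for r in hits)
            )
        return hits[0]

    def search(self, key: str) -> list[SegmentRecord]:
        parts = [p for p in key.split("/") if p]
        if not parts:
            return []
        age = parts[0].lower().replace("-", "")
        age = {"1year": "1y", "5year": "5y", "10year": "10y", "15year": "15y"}.get(age, age)
        rest = parts[1:]
        sex = "any"
        if rest and rest[0].lower() in ("male", "female", "m", "f"):
            sex = {"m": "male", "f": "female"}.get(rest[0].lower(), rest[0].lower())
            rest = rest[1:]
        hits = []
        for r in self.records:
            if r.age_group != age or (sex != "any" and r.sex not in ("any", sex)):
                continue
            if r.age_group in SEXED_AGES and sex == "any" and r.sex != "any":
                pass  # keep both sexes visible when none requested
            if rest:
                if normalize_name(rest[0]) != r.site_norm:
                    continue
                if len(rest) > 1 and normalize_name("/".join(rest[1:])) != r.segment_norm:
                    continue
            hits.append(r)
        return hits

    # -- census ------------------------------------------------------------

    def unique_records(self, age_group: str | None = None) -> list[SegmentRecord]:
        """Segment records with printed-identical male/female rows collapsed.

        For the sex-specific ages a record pair equal in every normalized
        parameter is one unique segment (unless flagged sex-distinct by a
        curation entry); the male copy represents it.
        """
        ages = [age_group] if age_group else list(AGE_GROUPS)
        out: list[SegmentRecord] = []
        for age in ages:
            recs = [r for r in self.records if r.age_group == age]
            if age not in SEXED_AGES:
                out.extend(recs)
                continue
            male_ids = {r.identity_tuple() for r in recs if r.sex == "male" and not r.sex_distinct}
            for r in recs:
                if r.sex == "male":
                    out.append(r)
                elif r.sex_distinct or r.identity_tuple() not in male_ids:
                    out.append(r)
        return out

    def count_unique_segments(self, scope: str = "all") -> int:
        age = None if scope == "all" else scope
        return len(self.unique_records(age))

    def shape_census(self, scope: str = "all") -> dict[str, int]:
        age = None if scope == "all" else scope
        census = {k: 0 for k in geometry.SHAPE_KINDS}
        for r in self.unique_records(age):
            census[r.shape] += 1
        return census

    def shared_segment_count(self, age_group: str) -> int:
        """Number of printed-identical male/female pairs counted once."""
        recs = [r for r in self.records if r.age_group == age_group]
        males = {r.identity_tuple() for r in recs if r.sex == "male" and not r.sex_distinct}
        return sum(1 for r in recs if r.sex == "female" and not r.sex_distinct and r.identity_tuple() in males)

    # -- validation ---------------------------------------------------------

    def validate(self) -> ValidationReport:
        rep = ValidationReport()
        for age, sex in PHANTOMS:
            dist = self.am_distribution(age, sex)
            total = dist.total()
            rep.add(f"am_sum_{age}_{sex}", abs(total - 100.0) <= 0.1 + 1e-9, f"sum={total:.2f}")

        bad: list[str] = []
        for r in self.records:
            dims = [v for v in (r.h, r.a, r.b, r.c, r.d) if v is not None]
            ok = all(v > 0 for v in dims) and 0 < r.bvtv < 1 and r.tb_th > 0 and r.tb_sp > 0
            if r.h is None or r.a is None or r.b is None:
                ok = False
            if ok:
                try:
                    spec = r.shape_spec()
                    for face, t in r.cortical:
                        if face not in spec.valid_faces() or t <= 0:
                            ok = False
                except geometry.ShapeError:
                    ok = False
            if r.shape != "deformed_cylinder" and (r.c is not None or r.d is not None):
                ok = False
            if not ok:
                bad.append(r.key)
        rep.add("record_invariants", not bad, "; ".join(bad[:8]))

        recs = [r for r in self.records if r.h is not None]
        bv_min = min(recs, key=lambda r: r.bvtv)
        bv_max = max(recs, key=lambda r: r.bvtv)
        rep.add(
            "min_bvtv",
            math.isclose(bv_min.bvtv, 0.06) and bv_min.site_norm == "humerus" and "proximal" in bv_min.segment_norm,
            f"{bv_min.bvtv} at {bv_min.key}",
        )
        rep.add(
            "max_bvtv",
            math.isclose(bv_max.bvtv, 0.6) and bv_max.age_group == "newborn" and bv_max.segment_norm == "cbody",
            f"{bv_max.bvtv} at {bv_max.key}",
        )
        cts = [(t, r) for r in self.records for _, t in r.cortical]
        ct_lo = min(cts, key=lambda p: p[0])[0]
        ct_hi = max(cts, key=lambda p: p[0])[0]
        rep.add("ct_th_range", math.isclose(ct_lo, 0.1) and math.isclose(ct_hi, 3.7), f"[{ct_lo}, {ct_hi}] mm")
        dims_all = [(v, r) for r in recs for v in (r.h, r.a, r.b, r.c, r.d) if v is not None]
        dmax, rmax = max(dims_all, key=lambda p: p[0])
        dmin, rmin = min(dims_all, key=lambda p: p[0])
        rep.add("max_linear_dimension", math.isclose(dmax, 88.0), f"{dmax} mm at {rmax.key}")
        rep.add("min_linear_dimension", math.isclose(dmin, 2.0), f"{dmin} mm at {rmin.key}")

        dens = [self._densities[a][0] for a in AGE_GROUPS]
        rep.add("bone_density_nondecreasing", all(x <= y for x, y in zip(dens, dens[1:])), str(dens))
        for medium, fracs in self.composition.items():
            s = sum(fracs.values())
            rep.add(f"composition_sum_{medium}", abs(s - 100.0) <= 0.5, f"sum={s:.2f}")

        if self.mode == "curated":
            rep.add("census_total", self.count_unique_segments() == 289, str(self.count_unique_segments()))
            expected = {"newborn": 34, "1y": 39, "5y": 43, "10y": 38}
            for age, n in expected.items():
                rep.add(f"census_{age}", self.count_unique_segments(age) == n, str(self.count_unique_segments(age)))
            shapes = self.shape_census()
            target = {"box": 142, "cylinder": 83, "deformed_cylinder": 56, "prism": 5, "ellipsoid": 1, "tube": 2}
            rep.add("census_shapes", shapes == target, str(shapes))
            rep.add("shared_15y", self.shared_segment_count("15y") == 28, str(self.shared_segment_count("15y")))
            rep.add("shared_adult", self.shared_segment_count("adult") == 23, str(self.shared_segment_count("adult")))
        return rep

    # -- export -------------------------------------------------------------

    def segments_table(self):
        """The records as a pandas DataFrame (lazy import keeps startup light)."""
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                {
                    "table_id": r.table_id,
                    "age_group": r.age_group,
                    "sex": r.sex,
                    "site": r.site,
                    "segment": r.segment,
                    "shape": SHAPE_LETTERS[r.shape],
                    "h": r.h,
                    "a": r.a,
                    "b": r.b,
                    "c": r.c,
                    "d": r.d,
                    "cortical": _format_cortical(r.cortical),
                    "bvtv": r.bvtv,
                    "tb_th": r.tb_th,
                    "sigma_tb_th": r.sigma_tb_th,
                    "tb_sp": r.tb_sp,
                    "sigma_tb_sp": r.sigma_tb_sp,
                    "n_s": r.n_s,
                    "k_s": r.k_s,
                }
            )
        return pd.DataFrame(rows)


def load_db(
    mode: str = "curated",
    multiplicity_overrides: dict[str, tuple[int, float]] | None = None,
) -> Database:
    """Load the embedded database in ``raw`` (as printed) or ``curated`` mode."""
    if mode not in ("raw", "curated"):
        raise DatabaseError(f"mode must be 'raw' or 'curated', got {mode!r}")

    records: list[SegmentRecord] = []
    lines = _read_resource("segments.tsv").splitlines()
    header = lines[0].split("\t")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise DatabaseError(f"segments.tsv line {lineno}: expected {len(header)} cells, got {len(cells)}")
        row = dict(zip(header, cells))
        try:
            records.append(
                SegmentRecord(
                    table_id=row["table_id"],
                    age_group=row["age_group"],
                    sex=row["sex"],
                    site=row["site"],
                    segment=row["segment"],
                    shape=SHAPE_CODES[row["shape"]],
                    h=_float_or_none(row["h"]),
                    a=_float_or_none(row["a"]),
                    b=_float_or_none(row["b"]),
                    c=_float_or_none(row["c"]),
                    d=_float_or_none(row["d"]),
                    cortical=_parse_cortical(row["cortical"]),
                    bvtv=float(row["bvtv"]),
                    tb_th=float(row["tb_th"]),
                    sigma_tb_th=float(row["sigma_tb_th"]),
                    tb_sp=float(row["tb_sp"]),
                    sigma_tb_sp=float(row["sigma_tb_sp"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise DatabaseError(f"segments.tsv line {lineno} ({row.get('site')}/{row.get('segment')}): {exc}") from exc

    curations = load_curations()
    if mode == "curated":
        for entry in curations:
            matched = False
            for i, rec in enumerate(records):
                if _curation_matches(rec, entry):
                    records[i] = _apply_curation(rec, entry)
                    matched = True
            if not matched:
                raise DatabaseError(f"curation entry matches no record: {entry}")

    rules = load_multiplicity_rules()
    records = [
        replace(r, n_s=n, k_s=k)
        for r in records
        for n, k in [resolve_multiplicity(r, rules, multiplicity_overrides)]
    ]

    am: dict[tuple[str, str], AMDistribution] = {}
    groups: dict[tuple[str, str], list] = {}
    for line in _read_resource("am_distribution.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        age, sex, sites, frac = line.split("\t")
        groups.setdefault((age, sex), []).append((tuple(sites.split(";")), float(frac)))
    for (age, sex), entries in groups.items():
        am[(age, sex)] = AMDistribution(age, sex, tuple(entries))

    densities: dict[str, tuple[float, float]] = {}
    for line in _read_resource("densities.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        age, bone, marrow = line.split("\t")
        densities[age] = (float(bone), float(marrow))

    composition: dict[str, dict[str, float]] = {"bone": {}, "bone_marrow": {}}
    for line in _read_resource("composition.tsv").splitlines()[1:]:
        if not line.strip():
            continue
        el, _massno, bone, marrow = line.split("\t")
        composition["bone"][el] = float(bone)
        composition["bone_marrow"][el] = float(marrow)

    return Database(mode, tuple(records), am, densities, composition, curations)
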