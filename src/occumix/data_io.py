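"""Reading, validating and standardizing study and detection-calibration tables.

The on-disk formats are plain UTF-8 CSV:

* **study CSV** — one row per site with columns
  ``site_id,set,work,dist,tree_1995,tree_2008,y_1995,y_2008,y_2009``.
  Empty cells encode *missing* (a survey that was not done); an explicit
  ``0`` is a survey in which no birds were seen, which is informative.
* **detection CSV** — one row per calibration site with columns
  ``site_id,count_1,count_2,count_3,count_4`` (four repeat visits within
  one closed season).

Covariates are centered and scaled by twice the sample standard deviation,
so binary and continuous effect sizes are directly comparable.  The two
tree-density eras share one coefficient in the model and are therefore
pooled into a single vector before scaling.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteSet",
    "SiteRecord",
    "DetectionStudy",
    "ScaledCovariate",
    "StudyDataset",
    "ParseError",
    "ValidationError",
    "DegenerateScaleError",
    "MissingCovariateError",
    "standardize",
    "covariate_for_year",
    "read_study",
    "write_study",
    "read_detection",
    "write_detection",
]

#: validation cap on observed counts; groups larger than this are biologically
#: implausible (observed range 1-10, hard cap 12) and flag a corrupt table.
MAX_COUNT = 12

STUDY_COLUMNS = (
    "site_id",
    "set",
    "work",
    "dist",
    "tree_1995",
    "tree_2008",
    "y_1995",
    "y_2008",
    "y_2009",
)

DETECTION_COLUMNS = ("site_id", "count_1", "count_2", "count_3", "count_4")


class ParseError(ValueError):
    """A CSV row could not be parsed."""


class ValidationError(ValueError):
    """A parsed record violates a dataset invariant."""


class DegenerateScaleError(ValueError):
    """Covariate vector has zero sample standard deviation."""


class MissingCovariateError(KeyError):
    """Requested a habitat covariate for a site that carries none."""


class SiteSet(enum.Enum):
    """Site stratum defined by detection history."""

    SET1 = "SET1"  # detected in the initial (1995) survey
    SET2 = "SET2"  # detected only in later incidental surveys
    SET3 = "SET3"  # surveyed 2008 + 2009 only; no habitat covariates


@dataclass(frozen=True)
class SiteRecord:
    """One study site: stratum, covariates and per-year counts.

    ``None`` counts mean the survey did not happen in that year.  SET3 sites
    carry no ``dist``/``tree`` covariates (their group-size submodel is
    intercept + works only).
    """

    site_id: str
    set: SiteSet
    work: int
    dist: float | None = None
    tree_1995: int | None = None
    tree_2008: int | None = None
    y_1995: int | None = None
    y_2008: int | None = None
    y_2009: int | None = None

    def validate(self, max_count: int = MAX_COUNT) -> None:
        sid = self.site_id
        if self.work not in (0, 1):
            raise ValidationError(f"site {sid!r}: work must be 0/1, got {self.work!r}")
        for name in ("y_1995", "y_2008", "y_2009"):
            y = getattr(self, name)
            if y is None:
                continue
            if not isinstance(y, (int, np.integer)) or isinstance(y, bool):
                raise ValidationError(f"site {sid!r}: {name} must be an integer count")
            if not 0 <= y <= max_count:
                raise ValidationError(
                    f"site {sid!r}: {name}={y} outside [0, {max_count}]"
                )
        if self.dist is not None and self.dist < 0:
            raise ValidationError(f"site {sid!r}: dist must be non-negative")
        for name in ("tree_1995", "tree_2008"):
            t = getattr(self, name)
            if t is not None and t < 0:
                raise ValidationError(f"site {sid!r}: {name} must be non-negative")

        if self.set is SiteSet.SET1:
            if self.y_1995 is None or self.y_1995 < 1:
                raise ValidationError(
                    f"site {sid!r}: SET1 requires y_1995 >= 1 (detected in 1995)"
                )
            self._require_covariates()
        elif self.set is SiteSet.SET2:
            if self.y_1995 is not None:
                raise ValidationError(
                    f"site {sid!r}: SET2 must not carry a 1995 count"
                )
            self._require_covariates()
        else:  # SET3
            if self.y_1995 is not None:
                raise ValidationError(f"site {sid!r}: SET3 must not carry a 1995 count")
            if self.y_2008 is None or self.y_2008 < 1:
                raise ValidationError(
                    f"site {sid!r}: SET3 requires y_2008 >= 1 (known occupied in 2008)"
                )
            if self.y_2009 is None:
                raise ValidationError(f"site {sid!r}: SET3 requires a 2009 count")
            if any(
                v is not None for v in (self.dist, self.tree_1995, self.tree_2008)
            ):
                raise ValidationError(
                    f"site {sid!r}: SET3 sites carry no habitat covariates"
                )

    def _require_covariates(self) -> None:
        missing = [
            n
            for n in ("dist", "tree_1995", "tree_2008")
            if getattr(self, n) is None
        ]
        if missing:
            raise ValidationError(
                f"site {self.site_id!r}: missing covariate(s) {missing}"
            )


@dataclass(frozen=True)
class DetectionStudy:
    """One calibration site: four repeat counts within a closed season."""

    site_id: str
    counts: tuple[int, int, int, int]

    def validate(self, max_count: int = MAX_COUNT) -> None:
        if len(self.counts) != 4:
            raise ValidationError(
                f"site {self.site_id!r}: expected 4 visit counts, got {len(self.counts)}"
            )
        for j, y in enumerate(self.counts, start=1):
            if not isinstance(y, (int, np.integer)) or y < 0 or y > max_count:
                raise ValidationError(
                    f"site {self.site_id!r}: visit {j} count {y!r} invalid"
                )


@dataclass(frozen=True)
class ScaledCovariate:
    """A covariate vector centered and divided by 2 x sample SD."""

    values: np.ndarray
    center: float
    scale: float

    def transform(self, x: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.scale


def standardize(values: Sequence[float]) -> ScaledCovariate:
    """Center ``values`` and scale by twice the (n-1) sample SD.

    The resulting vector has mean 0 and SD 0.5, putting continuous effects
    on the same footing as a binary indicator.

    Raises
    ------
    DegenerateScaleError
        If the vector is constant (or shorter than 2).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateScaleError("need at least 2 values to standardize")
    center = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd <= 0.0 or not math.isfinite(sd):
        raise DegenerateScaleError("covariate has zero sample standard deviation")
    scale = 2.0 * sd
    return ScaledCovariate(values=(x - center) / scale, center=center, scale=scale)


def covariate_for_year(site: SiteRecord, year: int) -> float:
    """Large-tree density applicable to a survey year.

    The 1995 habitat assessment applies to the 1995 survey; the 2008
    assessment applies to both the 2008 and 2009 surveys.
    """
    if site.set is SiteSet.SET3:
        raise MissingCovariateError(
            f"site {site.site_id!r} (SET3) carries no tree covariates"
        )
    if year == 1995:
        return float(site.tree_1995)
    if year in (2008, 2009):
        return float(site.tree_2008)
    raise ValueError(f"unknown survey year {year!r}")


@dataclass
class StudyDataset:
    """Validated collection of sites plus optional detection calibration data.

    ``scaling`` holds the centering/scaling constants for ``dist`` and the
    pooled ``tree`` densities so that model predictions "at the average
    site" (scaled covariate 0) stay well defined after the raw table is
    gone.
    """

    sites: list[SiteRecord]
    detection: list[DetectionStudy] = field(default_factory=list)
    scaling: dict[str, ScaledCovariate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate site_id(s): {dup}")
        if not self.scaling:
            self.scaling = compute_scaling(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sites_in(self, which: SiteSet) -> list[SiteRecord]:
        return [s for s in self.sites if s.set is which]

    def scaled_dist(self, site: SiteRecord) -> float:
        return float(self.scaling["dist"].transform(site.dist))

    def scaled_tree(self, site: SiteRecord, year: int) -> float:
        return float(self.scaling["tree"].transform(covariate_for_year(site, year)))


def compute_scaling(sites: Iterable[SiteRecord]) -> dict[str, ScaledCovariate]:
    """Scaling constants from the covariate-bearing (SET1/SET2) sites.

    The two tree-density eras share one regression coefficient, so both are
    pooled into a single vector before scaling.
    """
    cov_sites = [s for s in sites if s.set is not SiteSet.SET3]
    if not cov_sites:
        return {}
    dists = [s.dist for s in cov_sites]
    trees = [s.tree_1995 for s in cov_sites] + [s.tree_2008 for s in cov_sites]
    return {"dist": standardize(dists), "tree": standardize(trees)}


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


def _parse_int(cell: str, what: str, line_no: int) -> int | None:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise ParseError(f"line {line_no}: {what}={cell!r} is not an integer") from None


def _parse_float(cell: str, what: str, line_no: int) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"line {line_no}: {what}={cell!r} is not a number") from None


def read_study(
    path: str | Path,
    detection_path: str | Path | None = None,
    validate: bool = True,
    max_count: int = MAX_COUNT,
) -> StudyDataset:
    """Read a study CSV (and optional detection CSV) into a :class:`StudyDataset`.

    Raises :class:`ParseError` on malformed rows (naming the line) and
    :class:`ValidationError` on invariant violations (naming the site).
    ``max_count`` is the biological plausibility cap on counts; raise it for
    simulated data, whose group sizes are unbounded.
    """
    sites = _read_study_rows(Path(path).read_text(encoding="utf-8"))
    if validate:
        for s in sites:
            s.validate(max_count=max_count)
    detection: list[DetectionStudy] = []
    if detection_path is not None:
        detection = read_detection(detection_path, validate=validate,
                                   max_count=max_count)
    return StudyDataset(sites=sites, detection=detection)


def _read_study_rows(text: str) -> list[SiteRecord]:
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("line 1: empty file") from None
    if tuple(h.strip() for h in header) != STUDY_COLUMNS:
        raise ParseError(
            f"line 1: expected header {','.join(STUDY_COLUMNS)}, got {','.join(header)}"
        )
    sites = []
    for line_no, row in enumerate(reader, start=2):
        if not row or all(c == "" for c in row):
            continue
        if len(row) != len(STUDY_COLUMNS):
            raise ParseError(
                f"line {line_no}: expected {len(STUDY_COLUMNS)} fields, got {len(row)}"
            )
        cells = [c.strip() for c in row]
        try:
            site_set = SiteSet(cells[1])
        except ValueError:
            raise ParseError(f"line {line_no}: unknown set {cells[1]!r}") from None
        work = _parse_int(cells[2], "work", line_no)
        if work is None:
            raise ParseError(f"line {line_no}: work may not be empty")
        sites.append(
            SiteRecord(
                site_id=cells[0],
                set=site_set,
                work=work,
                dist=_parse_float(cells[3], "dist", line_no),
                tree_1995=_parse_int(cells[4], "tree_1995", line_no),
                tree_2008=_parse_int(cells[5], "tree_2008", line_no),
                y_1995=_parse_int(cells[6], "y_1995", line_no),
                y_2008=_parse_int(cells[7], "y_2008", line_no),
                y_2009=_parse_int(cells[8], "y_2009", line_no),
            )
        )
    return sites


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v) if v != int(v) else str(int(v))
    return str(v)


def write_study(dataset: StudyDataset, path: str | Path) -> None:
    """Write the study table; inverse of :func:`read_study` modulo column order."""
    lines = [",".join(STUDY_COLUMNS)]
    for s in dataset.sites:
        lines.append(
            ",".join(
                [
                    s.site_id,
                    s.set.value,
                    str(s.work),
                    _fmt(s.dist),
                    _fmt(s.tree_1995),
                    _fmt(s.tree_2008),
                    _fmt(s.y_1995),
                    _fmt(s.y_2008),
                    _fmt(s.y_2009),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_detection(
    path: str | Path, validate: bool = True, max_count: int = MAX_COUNT
) -> list[DetectionStudy]:
    reader = csv.reader(io.StringIO(Path(path).read_text(encoding="utf-8")))
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("line 1: empty file") from None
    if tuple(h.strip() for h in header) != DETECTION_COLUMNS:
        raise ParseError(
            f"line 1: expected header {','.join(DETECTION_COLUMNS)}, got {','.join(header)}"
        )
    out = []
    for line_no, row in enumerate(reader, start=2):
        if not row or all(c == "" for c in row):
            continue
        if len(row) != 5:
            raise ParseError(f"line {line_no}: expected 5 fields, got {len(row)}")
        cells = [c.strip() for c in row]
        counts = []
        for j, cell in enumerate(cells[1:], start=1):
            y = _parse_int(cell, f"count_{j}", line_no)
            if y is None:
                raise ParseError(f"line {line_no}: count_{j} may not be empty")
            counts.append(y)
        rec = DetectionStudy(site_id=cells[0], counts=tuple(counts))
        if validate:
            rec.validate(max_count=max_count)
        out.append(rec)
    return out


def write_detection(detection: Sequence[DetectionStudy], path: str | Path) -> None:
    lines = [",".join(DETECTION_COLUMNS)]
    for rec in detection:
        lines.append(",".join([rec.site_id] + [str(c) for c in rec.counts]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
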