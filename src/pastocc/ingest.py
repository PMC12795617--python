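"""Key-informant interview ingestion and detection-history construction.

Interviews with pastoralists act as repeated surveys of 5x5 km grid cells.
Each respondent is shown photographs of the focal species (look-alike pairs
for leopard/tiger and wolf/jackal) and asked about sightings in the focal
grid within the past year.  The identification flowchart classifies each
species response into a detection state:

    2  certain detection   (all paired look-alikes and the focal species
                            identified without a hint; valid in-grid,
                            within-year sighting)
    1  uncertain detection (focal species identified only with a hint, or a
                            look-alike misidentified; sighting still valid)
    0  non-detection       (identification fine but no valid sighting:
                            none reported, on/outside the grid border, or
                            older than one year)
    FAILED                 (focal species not identified even with a hint;
                            the interview is not a replicate for that
                            species)

Certain detections are taken to carry zero false-positive risk, so the
binary collapse used by the standard occupancy model keeps only state 2 as
a detection; uncertain detections become non-detections.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("leopard", "wolf", "hyena", "sloth_bear", "blackbuck")

#: look-alike photo sets shown alongside each focal species
PAIRED_SETS = {
    "leopard": ("tiger",),
    "wolf": ("jackal",),
    "hyena": (),
    "sloth_bear": (),
    "blackbuck": (),
}

FAILED = "FAILED"

ALL_SUBGRIDS = frozenset({1, 2, 3, 4})


class ValidationError(ValueError):
    """An interview record violates the survey protocol's invariants."""


class ReplicateStatus(str, enum.Enum):
    INDEPENDENT = "independent"
    NEEDS_PAIRING = "needs_pairing"
    INVALID = "invalid"


@dataclass(frozen=True)
class SpeciesResponse:
    """One respondent's answers about one focal species."""

    species: str
    paired_set_correct: tuple[bool, ...] = ()
    hint_used: bool = False
    focal_identified: bool = True
    sighting_reported: bool = False
    sighting_in_focal_grid: bool = False
    sighting_within_past_year: bool = False
    sighting_notes: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if not self.sighting_reported and (
            self.sighting_in_focal_grid or self.sighting_within_past_year
        ):
            raise ValidationError(
                f"{self.species}: sighting flags set without a reported sighting"
            )
        if not self.focal_identified and not self.hint_used:
            # a hint is always offered before an identification is abandoned
            raise ValidationError(
                f"{self.species}: focal_identified=False requires hint_used=True"
            )


@dataclass
class InterviewRecord:
    """One respondent (or merged pair) interviewed about one focal grid."""

    respondent_id: str
    focal_grid_id: str
    subgrids_covered: frozenset[int]
    years_experience: float
    merged_pair: bool = False
    responses: dict[str, SpeciesResponse] = field(default_factory=dict)
    _outcomes: dict[str, int | str] | None = None

    def __post_init__(self) -> None:
        self.subgrids_covered = frozenset(self.subgrids_covered)
        if not self.subgrids_covered <= ALL_SUBGRIDS:
            raise ValidationError(
                f"{self.respondent_id}: subgrids must be a subset of {{1,2,3,4}}"
            )
        if len(self.subgrids_covered) < 2:
            raise ValidationError(
                f"{self.respondent_id}: fewer than two subgrids covered; "
                "such interviews are never conducted"
            )
        if self.years_experience < 0:
            raise ValidationError(f"{self.respondent_id}: negative experience")

    @property
    def grid_covered(self) -> int:
        """Detection covariate: 1 iff the respondent covered all four subgrids."""
        return int(self.subgrids_covered == ALL_SUBGRIDS)

    def outcome(self, species: str) -> int | str | None:
        """Detection state for *species*, or None if the species was not asked."""
        if self._outcomes is not None:
            return self._outcomes.get(species)
        resp = self.responses.get(species)
        if resp is None:
            return None
        return classify_detection(resp)


@dataclass
class DetectionMatrix:
    """Per-species site x replicate detection states with ragged replicates.

    ``states`` holds {0, 1, 2} with NaN for missing replicates (including
    failed identifications).  The binary collapse keeps only certain
    detections: ``binary = 1`` iff ``states == 2``.
    """

    species: str
    site_ids: list[str]
    states: np.ndarray  # (n_sites, max_replicates), float with NaN
    detection_covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        valid = np.isnan(self.states) | np.isin(self.states, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValidationError(f"{self.species}: states outside {{0,1,2,NaN}}")
        for name, arr in self.detection_covariates.items():
            if np.asarray(arr).shape != self.states.shape:
                raise ValidationError(
                    f"detection covariate {name!r} shape mismatch"
                )

    @property
    def n_sites(self) -> int:
        return self.states.shape[0]

    @property
    def binary(self) -> np.ndarray:
        return collapse_to_binary(self.states, already_binary=False)

    @property
    def replicate_counts(self) -> np.ndarray:
        return (~np.isnan(self.states)).sum(axis=1)


def collapse_to_binary(
    states: np.ndarray, already_binary: bool | None = None
) -> np.ndarray:
    """Certain detections (2) -> 1; uncertain (1) and non-detections (0) -> 0.

    NaN (missing) propagates.  With ``already_binary=None`` (default) an
    input whose values all lie in {0, 1} is treated as an already-collapsed
    binary layer and returned unchanged, making the collapse idempotent;
    pass ``already_binary=False`` to force three-state semantics (used by
    :attr:`DetectionMatrix.binary`, where 1 always means *uncertain*).
    """
    states = np.asarray(states, dtype=float)
    if already_binary is None:
        observed = states[~np.isnan(states)]
        already_binary = bool(np.isin(observed, (0.0, 1.0)).all())
    if already_binary:
        return states.copy()
    out = np.where(states == 2.0, 1.0, 0.0)
    out[np.isnan(states)] = np.nan
    return out


def classify_detection(resp: SpeciesResponse) -> int | str:
    """Apply the identification flowchart to one species response.

    Returns 2 (certain), 1 (uncertain), 0 (non-detection) or ``FAILED``.
    """
    if not resp.focal_identified:
        return FAILED
    valid_sighting = (
        resp.sighting_reported
        and resp.sighting_in_focal_grid
        and resp.sighting_within_past_year
    )
    if not valid_sighting:
        return 0
    if all(resp.paired_set_correct) and not resp.hint_used:
        return 2
    return 1


def validate_replicate(subgrids: frozenset[int] | set[int]) -> ReplicateStatus:
    """Classify an interview by subgrid coverage.

    At least three of four subgrids makes an independent replicate; exactly
    two requires pairing with a complementary respondent; fewer than two is
    invalid (no interview would have been conducted).
    """
    n = len(set(subgrids))
    if n >= 3:
        return ReplicateStatus.INDEPENDENT
    if n == 2:
        return ReplicateStatus.NEEDS_PAIRING
    return ReplicateStatus.INVALID


def combine_outcomes(a: int | str | None, b: int | str | None) -> int | str | None:
    """Merge rule for paired interviews: FAILED dominates, else max state."""
    if a is None or b is None:
        return a if b is None else b
    if a == FAILED or b == FAILED:
        return FAILED
    return max(int(a), int(b))


def merge_paired(a: InterviewRecord, b: InterviewRecord) -> InterviewRecord:
    """Combine two partial-coverage interviews into one replicate.

    The merged record keeps the union of subgrids (must reach three), the
    longer herding experience, and per species the combined outcome: FAILED
    if either respondent failed the identification, otherwise the higher
    certainty state.
    """
    if a.focal_grid_id != b.focal_grid_id:
        raise ValidationError(
            f"cannot merge interviews for different grids "
            f"({a.focal_grid_id!r} vs {b.focal_grid_id!r})"
        )
    union = a.subgrids_covered | b.subgrids_covered
    if len(union) < 3:
        raise ValidationError(
            f"merged interviews {a.respondent_id}+{b.respondent_id} still cover "
            f"only {sorted(union)}; at least three subgrids required"
        )
    outcomes: dict[str, int | str] = {}
    for sp in SPECIES:
        merged = combine_outcomes(a.outcome(sp), b.outcome(sp))
        if merged is not None:
            outcomes[sp] = merged
    return InterviewRecord(
        respondent_id=f"{a.respondent_id}+{b.respondent_id}",
        focal_grid_id=a.focal_grid_id,
        subgrids_covered=union,
        years_experience=max(a.years_experience, b.years_experience),
        merged_pair=True,
        responses={},
        _outcomes=outcomes,
    )


def prepare_records(records: list[InterviewRecord]) -> list[InterviewRecord]:
    """Resolve pairing: keep independent replicates, merge complementary
    two-subgrid interviews within each grid (greedy, in ingestion order).

    Unpairable two-subgrid interviews are dropped with a warning.
    """
    out: list[InterviewRecord] = []
    pending: dict[str, list[InterviewRecord]] = {}
    for rec in records:
        status = validate_replicate(rec.subgrids_covered)
        if status is ReplicateStatus.INDEPENDENT:
            out.append(rec)
            continue
        queue = pending.setdefault(rec.focal_grid_id, [])
        partner_idx = next(
            (
                i
                for i, other in enumerate(queue)
                if len(other.subgrids_covered | rec.subgrids_covered) >= 3
            ),
            None,
        )
        if partner_idx is None:
            queue.append(rec)
        else:
            out.append(merge_paired(queue.pop(partner_idx), rec))
    for grid_id, queue in pending.items():
        for rec in queue:
            logger.warning(
                "dropping unpaired two-subgrid interview %s in grid %s",
                rec.respondent_id,
                grid_id,
            )
    return out


def build_detection_matrix(
    records: list[InterviewRecord],
    species: str,
    max_replicates: int = 7,
) -> DetectionMatrix:
    """Assemble the site x replicate state matrix for one species.

    Records must already be validated/merged (see :func:`prepare_records`).
    FAILED identifications become missing cells for this species only; a
    site whose replicates are all missing is dropped with a warning, which
    is why per-species site counts may differ.
    """
    by_site: dict[str, list[InterviewRecord]] = {}
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.focal_grid_id, rec.respondent_id)
        if key in seen:
            raise ValidationError(f"duplicate (site, replicate) key {key}")
        seen.add(key)
        by_site.setdefault(rec.focal_grid_id, []).append(rec)

    site_ids: list[str] = []
    rows: list[list[float]] = []
    cov_rows: dict[str, list[list[float]]] = {"grid_covered": [], "experience": []}
    for grid_id, recs in by_site.items():
        if len(recs) > max_replicates:
            raise ValidationError(
                f"site {grid_id} has {len(recs)} replicates "
                f"(configured maximum {max_replicates})"
            )
        states, covered, exper = [], [], []
        for rec in recs:
            out = rec.outcome(species)
            if out is None or out == FAILED:
                states.append(np.nan)
                covered.append(np.nan)
                exper.append(np.nan)
            else:
                states.append(float(out))
                covered.append(float(rec.grid_covered))
                exper.append(float(rec.years_experience))
        if np.isnan(states).all():
            logger.warning(
                "site %s has no usable replicates for %s; dropped", grid_id, species
            )
            continue
        site_ids.append(grid_id)
        rows.append(states)
        cov_rows["grid_covered"].append(covered)
        cov_rows["experience"].append(exper)

    if not site_ids:
        raise ValidationError(f"no sites with usable replicates for {species}")

    width = max(len(r) for r in rows)

    def _pad(rowlist: list[list[float]]) -> np.ndarray:
        arr = np.full((len(rowlist), width), np.nan)
        for i, r in enumerate(rowlist):
            arr[i, : len(r)] = r
        return arr

    return DetectionMatrix(
        species=species,
        site_ids=site_ids,
        states=_pad(rows),
        detection_covariates={k: _pad(v) for k, v in cov_rows.items()},
    )


def naive_occupancy(m: DetectionMatrix) -> float:
    """Fraction of sites with at least one (binary) detection.

    Ignores imperfect detection, so it lower-bounds the null-model
    occupancy estimate.
    """
    if m.n_sites == 0:
        raise ValueError("empty detection matrix")
    detected = np.nansum(m.binary, axis=1) > 0
    return detected.sum() / m.n_sites


def site_summary(m: DetectionMatrix) -> pd.DataFrame:
    """Per-site replicate and detection counts plus the overall naive occupancy."""
    binary = m.binary
    df = pd.DataFrame(
        {
            "site_id": m.site_ids,
            "n_replicates": m.replicate_counts,
            "n_detections": np.nansum(binary, axis=1).astype(int),
        }
    )
    df.attrs["naive_occupancy"] = naive_occupancy(m)
    return df


# ---------------------------------------------------------------------------
# delimited-text I/O

_RESPONSE_FIELDS = (
    "paired_correct",
    "hint_used",
    "focal_identified",
    "sighting_reported",
    "sighting_in_focal_grid",
    "sighting_within_past_year",
    "notes",
)


def _bool(x: str) -> bool:
    return str(x).strip() in ("1", "True", "true", "TRUE")


def interview_columns() -> list[str]:
    cols = [
        "respondent_id",
        "focal_grid_id",
        "subgrids_covered",
        "years_experience",
        "merged_pair",
    ]
    for sp in SPECIES:
        cols += [f"{sp}_{f}" for f in _RESPONSE_FIELDS]
    return cols


def read_interviews(path) -> list[InterviewRecord]:
    """Load interview records from the CSV schema written by
    :func:`write_interviews`; the schema is validated on load."""
    records: list[InterviewRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(interview_columns()) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"interview file missing columns: {sorted(missing)}")
        for row in reader:
            responses = {}
            for sp in SPECIES:
                if row[f"{sp}_focal_identified"] == "":
                    continue  # species not asked
                paired_raw = row[f"{sp}_paired_correct"]
                paired = (
                    tuple(_bool(t) for t in paired_raw.split("|"))
                    if paired_raw
                    else ()
                )
                responses[sp] = SpeciesResponse(
                    species=sp,
                    paired_set_correct=paired,
                    hint_used=_bool(row[f"{sp}_hint_used"]),
                    focal_identified=_bool(row[f"{sp}_focal_identified"]),
                    sighting_reported=_bool(row[f"{sp}_sighting_reported"]),
                    sighting_in_focal_grid=_bool(row[f"{sp}_sighting_in_focal_grid"]),
                    sighting_within_past_year=_bool(
                        row[f"{sp}_sighting_within_past_year"]
                    ),
                    sighting_notes=row[f"{sp}_notes"],
                )
            records.append(
                InterviewRecord(
                    respondent_id=row["respondent_id"],
                    focal_grid_id=row["focal_grid_id"],
                    subgrids_covered=frozenset(
                        int(t) for t in row["subgrids_covered"].split("|") if t
                    ),
                    years_experience=float(row["years_experience"]),
                    merged_pair=_bool(row["merged_pair"]),
                    responses=responses,
                )
            )
    return records


def write_interviews(records: list[InterviewRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=interview_columns())
        writer.writeheader()
        for rec in records:
            row = {
                "respondent_id": rec.respondent_id,
                "focal_grid_id": rec.focal_grid_id,
                "subgrids_covered": "|".join(str(s) for s in sorted(rec.subgrids_covered)),
                "years_experience": rec.years_experience,
                "merged_pair": int(rec.merged_pair),
            }
            for sp in SPECIES:
                resp = rec.responses.get(sp)
                if resp is None:
                    row.update({f"{sp}_{f}": "" for f in _RESPONSE_FIELDS})
                    continue
                row[f"{sp}_paired_correct"] = "|".join(
                    str(int(b)) for b in resp.paired_set_correct
                )
                row[f"{sp}_hint_used"] = int(resp.hint_used)
                row[f"{sp}_focal_identified"] = int(resp.focal_identified)
                row[f"{sp}_sighting_reported"] = int(resp.sighting_reported)
                row[f"{sp}_sighting_in_focal_grid"] = int(resp.sighting_in_focal_grid)
                row[f"{sp}_sighting_within_past_year"] = int(
                    resp.sighting_within_past_year
                )
                row[f"{sp}_notes"] = resp.sighting_notes
            writer.writerow(row)


def write_detection_history(m: DetectionMatrix, path) -> None:
    """Export the states and binary layers as one delimited file."""
    width = m.states.shape[1]
    cols = {"site_id": m.site_ids}
    for j in range(width):
        cols[f"state_{j + 1}"] = m.states[:, j]
    binary = m.binary
    for j in range(width):
        cols[f"binary_{j + 1}"] = binary[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
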