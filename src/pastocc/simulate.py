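"""Synthetic landscapes and key-informant interview surveys.

The generator emulates the study design the pipeline assumes: a district of
5x5 km grid cells of which roughly half are sampled; one to seven interview
replicates per sampled cell; logit-linear occupancy and detection on
standardized covariates; a certainty split of true detections (certain vs
uncertain); rare uncertain false positives at unoccupied sites (certain
detections are never false); occasional failed identifications; and
two-subgrid interviews that must be merged with a complementary partner.

It emits the same interview and covariate file formats the ingestion
modules consume, together with a complete truth log, so every pipeline
stage can be checked against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import ingest
from .covariates import CovariateTable, build_covariate_table
from .ingest import ALL_SUBGRIDS, InterviewRecord, SpeciesResponse

#: latent linear mapping for each covariate field: value = loc + scale * z,
#: clipped to the stated bounds (areas cannot exceed the 25 km^2 cell)
_FIELD_PARAMS = {
    "area_kharif": (8.0, 3.0, 0.0, 25.0),
    "area_double_triple": (5.0, 2.5, 0.0, 25.0),
    "area_one": (6.0, 3.0, 0.0, 25.0),
    "road_length": (10.0, 4.0, 0.0, None),
    "biomass_small": (60_000.0, 20_000.0, 0.0, None),
    "biomass_large": (150_000.0, 50_000.0, 0.0, None),
}

_COV_NAME = {
    "kharif": "area_kharif",
    "double_triple": "area_double_triple",
    "one": "area_one",
    "road": "road_length",
    "biomass_small": "biomass_small",
    "biomass_large": "biomass_large",
}


@dataclass
class SimConfig:
    """Study-scale defaults: 119 sampled cells of a 230-cell district,
    1-6 interviews per cell, occupancy near 0.5 and per-replicate detection
    near 0.3."""

    species: str = "hyena"
    n_grids: int = 230
    n_sampled: int = 119
    replicate_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.20, 3: 0.30, 4: 0.20, 5: 0.15, 6: 0.05}
    )
    beta_psi: dict[str, float] = field(
        default_factory=lambda: {"(Intercept)": 0.0, "one": 0.8}
    )
    alpha_p: dict[str, float] = field(
        default_factory=lambda: {"(Intercept)": -0.85, "experience": 0.5}
    )
    certainty: float = 0.85  # P(certain | true detection)
    false_positive: float = 0.02  # P(uncertain detection | unoccupied), per replicate
    failed_rate: float = 0.03  # P(failed identification), per interview
    covariate_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    paired_fraction: float = 0.10  # share of replicates built from two merged interviews
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_grids < 2 or not 2 <= self.n_sampled <= self.n_grids:
            raise ValueError("need at least two grids and 2 <= n_sampled <= n_grids")
        total = sum(self.replicate_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"replicate-count probabilities sum to {total}, not 1")
        if not all(1 <= k <= 7 for k in self.replicate_probs):
            raise ValueError("replicate counts must lie in 1..7")
        for name, v in (
            ("certainty", self.certainty),
            ("false_positive", self.false_positive),
            ("failed_rate", self.failed_rate),
            ("paired_fraction", self.paired_fraction),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for one simulated survey."""

    psi: pd.Series  # per sampled grid
    z: pd.Series  # realized occupancy state
    p: np.ndarray  # (n_sampled, max_reps) true detection probability, NaN-padded
    states: np.ndarray  # realized detection states {0,1,2}, NaN-padded
    site_ids: list[str]
    n_detections: int = 0
    n_certain: int = 0
    n_uncertain_true: int = 0
    n_false_positive: int = 0
    n_failed: int = 0


def _corr_matrix(names: list[str], corr: dict[tuple[str, str], float]) -> np.ndarray:
    d = len(names)
    R = np.eye(d)
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), r in corr.items():
        fa, fb = _COV_NAME.get(a, a), _COV_NAME.get(b, b)
        if fa not in idx or fb not in idx:
            raise KeyError(f"unknown covariate in correlation target ({a}, {b})")
        R[idx[fa], idx[fb]] = R[idx[fb], idx[fa]] = r
    # infeasible targets show up as a non-PD correlation matrix
    try:
        np.linalg.cholesky(R + 1e-12 * np.eye(d))
    except np.linalg.LinAlgError:
        raise ValueError("infeasible covariate correlation target (matrix not PD)")
    return R


def simulate_landscape(cfg: SimConfig) -> tuple[pd.DataFrame, CovariateTable]:
    """Generate the district grid with correlated covariate fields.

    Returns the raw grid table (one row per cell, `sampled` flag and
    `water_fraction` included) and the standardized, screened covariate
    table built from it.  Byte-identical across runs for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(_FIELD_PARAMS)
    R = _corr_matrix(names, cfg.covariate_corr)
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((cfg.n_grids, len(names))) @ chol.T

    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        loc, scale, lo, hi = _FIELD_PARAMS[name]
        data[name] = np.clip(loc + scale * z[:, j], lo, hi if hi is not None else np.inf)

    # a handful of cells are dominated by waterbodies (surface-exclusion rule)
    u = rng.random(cfg.n_grids)
    water = np.where(u < 0.04, rng.uniform(0.76, 0.95, cfg.n_grids),
                     np.where(u < 0.10, rng.uniform(0.0, 0.5, cfg.n_grids), 0.0))

    grid_ids = [f"G{i + 1:03d}" for i in range(cfg.n_grids)]
    sampled = np.zeros(cfg.n_grids, dtype=bool)
    # sample only cells not dominated by water, mimicking the survey design
    eligible = np.flatnonzero(water <= 0.5)
    chosen = rng.choice(eligible, size=min(cfg.n_sampled, eligible.size), replace=False)
    sampled[chosen] = True

    df = pd.DataFrame({"grid_id": grid_ids, **data})
    df["fraction_in_district"] = 1.0
    df["water_fraction"] = water
    df["sampled"] = sampled
    cov = build_covariate_table(df)
    return df, cov


def _linear(z_row: pd.Series, coefs: dict[str, float], extra: dict[str, float]) -> float:
    eta = coefs.get("(Intercept)", 0.0)
    for name, b in coefs.items():
        if name == "(Intercept)":
            continue
        if name in extra:
            eta += b * extra[name]
        else:
            eta += b * float(z_row[name])
    return eta


def _response_for_state(species: str, state, rng: np.random.Generator) -> SpeciesResponse:
    """Construct interview flags whose classification yields *state*."""
    paired_n = len(ingest.PAIRED_SETS[species])
    ok = (True,) * paired_n
    if state == ingest.FAILED:
        return SpeciesResponse(
            species=species, paired_set_correct=ok, hint_used=True,
            focal_identified=False,
        )
    state = int(state)
    if state == 2:
        return SpeciesResponse(
            species=species, paired_set_correct=ok, hint_used=False,
            focal_identified=True, sighting_reported=True,
            sighting_in_focal_grid=True, sighting_within_past_year=True,
        )
    if state == 1:
        # uncertainty comes from a needed hint or, where a look-alike pair
        # exists, a misidentified pair member
        if paired_n and rng.random() < 0.5:
            paired = (False,) + (True,) * (paired_n - 1)
            hint = False
        else:
            paired, hint = ok, True
        return SpeciesResponse(
            species=species, paired_set_correct=paired, hint_used=hint,
            focal_identified=True, sighting_reported=True,
            sighting_in_focal_grid=True, sighting_within_past_year=True,
        )
    # non-detection: usually nothing reported, sometimes a border/old sighting
    u = rng.random()
    if u < 0.75:
        return SpeciesResponse(
            species=species, paired_set_correct=ok, focal_identified=True
        )
    if u < 0.9:
        return SpeciesResponse(
            species=species, paired_set_correct=ok, focal_identified=True,
            sighting_reported=True, sighting_in_focal_grid=False,
            sighting_within_past_year=True, sighting_notes="border sighting",
        )
    return SpeciesResponse(
        species=species, paired_set_correct=ok, focal_identified=True,
        sighting_reported=True, sighting_in_focal_grid=True,
        sighting_within_past_year=False, sighting_notes="older than one year",
    )


def simulate_survey(
    cfg: SimConfig, landscape: tuple[pd.DataFrame, CovariateTable] | None = None
) -> tuple[list[InterviewRecord], SimTruth]:
    """Simulate interview records for the focal species plus the truth log.

    Occupancy: z_i ~ Bernoulli(psi_i) with psi logit-linear in the
    standardized site covariates.  Detection per replicate at occupied
    sites: detect with probability p_ij, record certain with probability
    `certainty` else uncertain.  Unoccupied sites yield uncertain false
    positives with probability `false_positive`.  Failed identifications
    are injected at `failed_rate` and a `paired_fraction` of replicates is
    emitted as two complementary two-subgrid interviews.
    """
    if landscape is None:
        landscape = simulate_landscape(cfg)
    grid_df, cov = landscape
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))

    zcov = cov.z()
    sampled_ids = list(grid_df.loc[grid_df["sampled"].to_numpy(), "grid_id"])
    counts = sorted(cfg.replicate_probs)
    probs = np.array([cfg.replicate_probs[k] for k in counts])
    max_reps = max(counts)

    psi_vals, z_vals = {}, {}
    p_arr = np.full((len(sampled_ids), max_reps), np.nan)
    s_arr = np.full((len(sampled_ids), max_reps), np.nan)
    records: list[InterviewRecord] = []
    tallies = dict(det=0, certain=0, uncertain=0, fp=0, failed=0)
    rid = 0

    for i, gid in enumerate(sampled_ids):
        zrow = zcov.loc[gid]
        psi = expit(_linear(zrow, cfg.beta_psi, {}))
        z = rng.random() < psi
        psi_vals[gid], z_vals[gid] = psi, int(z)
        n_reps = int(rng.choice(counts, p=probs))

        for j in range(n_reps):
            exp_z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            years = 22.5 + 8.0 * exp_z  # raw years; ingestion re-standardizes
            if rng.random() < cfg.paired_fraction:
                subgrid_sets = _complementary_pair(rng)
            else:
                n_sub = 4 if rng.random() < 0.55 else 3
                subgrid_sets = [frozenset(rng.choice(4, n_sub, replace=False) + 1)]
            covered = 1.0 if frozenset().union(*subgrid_sets) == ALL_SUBGRIDS else 0.0

            p = expit(
                _linear(zrow, cfg.alpha_p, {"experience": exp_z, "grid_covered": covered})
            )
            p_arr[i, j] = p

            if rng.random() < cfg.failed_rate:
                state: int | str = ingest.FAILED
                tallies["failed"] += 1
            elif z:
                if rng.random() < p:
                    if rng.random() < cfg.certainty:
                        state = 2
                        tallies["certain"] += 1
                    else:
                        state = 1
                        tallies["uncertain"] += 1
                    tallies["det"] += 1
                else:
                    state = 0
            else:
                if rng.random() < cfg.false_positive:
                    state = 1
                    tallies["fp"] += 1
                else:
                    state = 0
            s_arr[i, j] = np.nan if state == ingest.FAILED else float(state)

            if len(subgrid_sets) == 1:
                rid += 1
                records.append(
                    InterviewRecord(
                        respondent_id=f"R{rid:05d}",
                        focal_grid_id=gid,
                        subgrids_covered=subgrid_sets[0],
                        years_experience=round(max(years, 1.0), 1),
                        responses={
                            cfg.species: _response_for_state(cfg.species, state, rng)
                        },
                    )
                )
            else:
                # the replicate's state and the longer experience go to one
                # member; the partner contributes a non-detection so the
                # merge reproduces the intended replicate exactly
                partner_years = round(max(years - rng.uniform(1, 10), 1.0), 1)
                for k, (sub, st, yr) in enumerate(
                    zip(subgrid_sets, (state, 0), (round(max(years, 1.0), 1), partner_years))
                ):
                    rid += 1
                    records.append(
                        InterviewRecord(
                            respondent_id=f"R{rid:05d}",
                            focal_grid_id=gid,
                            subgrids_covered=sub,
                            years_experience=yr,
                            responses={
                                cfg.species: _response_for_state(cfg.species, st, rng)
                            },
                        )
                    )

    truth = SimTruth(
        psi=pd.Series(psi_vals),
        z=pd.Series(z_vals),
        p=p_arr,
        states=s_arr,
        site_ids=sampled_ids,
        n_detections=tallies["det"],
        n_certain=tallies["certain"],
        n_uncertain_true=tallies["uncertain"],
        n_false_positive=tallies["fp"],
        n_failed=tallies["failed"],
    )
    return records, truth


def _complementary_pair(rng: np.random.Generator) -> list[frozenset[int]]:
    """Two two-subgrid coverages whose union has at least three subgrids."""
    perm = [int(x) + 1 for x in rng.permutation(4)]
    first = frozenset(perm[:2])
    if rng.random() < 0.5:
        second = frozenset(perm[2:])  # disjoint halves: union covers the grid
    else:
        second = frozenset({perm[2], perm[0]})  # overlapping: union of three
    return [first, second]


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryReport:
    n_reps: int
    psi_true: float
    psi_bias: float
    psi_rmse: float
    psi_coverage: float
    p_true: float
    p_bias: float
    p_coverage: float
    naive_mean: float
    selection_hits: dict[str, float] = field(default_factory=dict)
    n_failed_fits: int = 0


def recovery_experiment(
    cfg: SimConfig,
    n_reps: int,
    seed: int = 0,
    select: bool = False,
    p_menu: tuple[str, ...] = (),
    psi_menu: tuple[str, ...] = (),
    B: int = 25,
    n_starts: int = 4,
) -> RecoveryReport:
    """Repeatedly simulate, ingest and fit; report estimator bias, RMSE and
    Wald 95% interval coverage, plus — with ``select=True`` — how often the
    generating covariates enter the retained model sets.

    With covariate-free generating parameters the "truth" for psi and p is
    the constant generating value; psi is compared against the binary
    (certain-detections-only) process, i.e. effective detection
    p * certainty.
    """
    from .occupancy import ModelSpec, align_covariates, fit_occupancy
    from .selection import two_step_select

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence((seed, 99))
    child_seeds = ss.generate_state(n_reps) % (2**31 - 1)

    psi_true = float(expit(cfg.beta_psi.get("(Intercept)", 0.0)))
    p_true_binary = float(expit(cfg.alpha_p.get("(Intercept)", 0.0))) * cfg.certainty

    psi_hats, psi_cover, p_hats, p_cover, naives = [], [], [], [], []
    hits = {"psi": 0, "p": 0}
    n_sel = 0
    n_failed = 0

    for r in range(n_reps):
        rcfg = replace(cfg, seed=int(child_seeds[r]))
        landscape = simulate_landscape(rcfg)
        records, _ = simulate_survey(rcfg, landscape)
        prepared = ingest.prepare_records(records)
        m = ingest.build_detection_matrix(prepared, rcfg.species)
        cov = align_covariates(landscape[1], m)
        naives.append(ingest.naive_occupancy(m))

        if select:
            try:
                res = two_step_select(
                    m, cov, p_menu, psi_menu,
                    B=B, seed=int(child_seeds[r]), n_starts=n_starts,
                )
            except ValueError:
                n_failed += 1
                continue
            n_sel += 1
            gen_psi = [c for c in cfg.beta_psi if c != "(Intercept)"]
            gen_p = [c for c in cfg.alpha_p if c != "(Intercept)"]
            if all(
                any(c in f.spec.psi_covariates for f in res.psi_ladder.retained)
                for c in gen_psi
            ):
                hits["psi"] += 1
            if all(
                any(c in f.spec.p_covariates for f in res.p_ladder.retained)
                for c in gen_p
            ):
                hits["p"] += 1
            fit = res.psi_ladder.best
        else:
            fit = fit_occupancy(m, cov, ModelSpec(), n_starts=n_starts,
                                seed=int(child_seeds[r]))
        if not fit.converged:
            n_failed += 1
            continue

        b0, a0 = fit.beta_psi["(Intercept)"], fit.beta_p["(Intercept)"]
        se_b0, se_a0 = fit.se_psi["(Intercept)"], fit.se_p["(Intercept)"]
        psi_hats.append(float(expit(b0)))
        p_hats.append(float(expit(a0)))
        lo, hi = expit(b0 - 1.96 * se_b0), expit(b0 + 1.96 * se_b0)
        psi_cover.append(lo <= psi_true <= hi)
        lo, hi = expit(a0 - 1.96 * se_a0), expit(a0 + 1.96 * se_a0)
        p_cover.append(lo <= p_true_binary <= hi)

    psi_hats = np.array(psi_hats)
    p_hats = np.array(p_hats)
    return RecoveryReport(
        n_reps=n_reps,
        psi_true=psi_true,
        psi_bias=float(psi_hats.mean() - psi_true) if psi_hats.size else np.nan,
        psi_rmse=float(np.sqrt(((psi_hats - psi_true) ** 2).mean()))
        if psi_hats.size else np.nan,
        psi_coverage=float(np.mean(psi_cover)) if psi_cover else np.nan,
        p_true=p_true_binary,
        p_bias=float(p_hats.mean() - p_true_binary) if p_hats.size else np.nan,
        p_coverage=float(np.mean(p_cover)) if p_cover else np.nan,
        naive_mean=float(np.mean(naives)) if naives else np.nan,
        selection_hits={k: v / n_sel for k, v in hits.items()} if n_sel else {},
        n_failed_fits=n_failed,
    )
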