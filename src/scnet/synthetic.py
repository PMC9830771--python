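"""Synthetic cohorts with known covariance structure.

Real structural-covariance studies start from per-subject regional
grey-matter volumes.  Because such tables are rarely deposited, this
module generates cohorts whose *population* covariance is fully
specified, so every downstream stage (residualization, correlation
networks, density thresholding, graph metrics, permutation inference)
can be tested against ground truth.

The generative model per subject is

    volume_r = mu + beta_age * (age - age_mean) + beta_sex * (sex - 1/2) + eps_r

with ``eps ~ MVN(0, noise_sd^2 * R)`` and ``R`` a block-structured
correlation matrix: regions fall into blocks with within-block
correlation ``rho_in`` and between-block correlation ``rho_out``; one
optional *hub* region may receive an elevated correlation ``rho_hub``
to every other region, giving it high betweenness in the thresholded
network.  Group 2 can carry per-region correlation perturbations
(``group_effect``), which is how between-group network differences are
implanted.  Longitudinal designs draw, per subject, a baseline and a
follow-up residual vector with within-subject (test-retest)
correlation ``rho_t``.

All correlation parameters must leave the implied population matrix
positive semi-definite; a violation raises
:class:`~scnet.errors.SpecificationError` (no silent nearest-PSD
repair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import SpecificationError
from .volumes import BASELINE, FOLLOWUP, METADATA_COLUMNS, aal116_labels

_PSD_TOL = 1e-10

GROUP_LABELS = ("control", "patient")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic cohort.

    Parameters
    ----------
    n_regions
        Number of brain regions (default 116, the AAL parcellation).
    n_subjects_per_group
        Subjects per group (default 20, a typical first-episode cohort).
    block_sizes
        Sizes of the covariance blocks; must sum to ``n_regions``.
        ``None`` partitions regions into blocks of 6 (last block takes
        the remainder), a coarse stand-in for lobar covariance
        communities.
    rho_in, rho_out
        Within-block and between-block population correlations.
    hub_region, rho_hub
        Optional region index given correlation ``rho_hub`` to every
        other region, implanting a covariance hub.  ``rho_hub`` cannot
        exceed roughly the square root of the mean background
        correlation before the matrix loses positive
        semi-definiteness, which caps realistic hub strengths.
    group_effect
        Mapping region index -> additive correlation perturbation for
        group 2.  With the default ``group_effect_scope="bridge"`` the
        perturbation applies to the target's correlations with one
        region in each of up to 6 *other* blocks, turning the target
        into a cross-community connector -- the kind of change that
        moves betweenness centrality.  ``"block"`` shifts the target's
        within-block correlations instead (changes edge ranks but
        rarely graph topology), and ``"all"`` shifts the whole row,
        which is PSD-feasible only for small shifts or few regions (a
        uniform row shift ``delta`` contributes a negative eigenvalue
        of about ``-delta * sqrt(n_regions)``).
    group_effect_scope
        ``"bridge"`` (default), ``"block"`` or ``"all"``; see above.
    age_slope
        Volume change per year of age (arbitrary volume units/year;
        negative by default, as grey matter shrinks with age).
    sex_offset
        Additive volume difference of sex==1 relative to sex==0.
    longitudinal
        If True, each subject gets a baseline and a follow-up row.
    rho_t
        Within-subject test-retest correlation of the residuals.
    followup_change
        Mean volume change at follow-up (scalar, or per-region array).
    noise_sd
        Residual volume standard deviation (volume units).
    mean_volume
        Grand mean regional volume (arbitrary units).
    age_mean, age_sd
        Population age distribution (years).
    seed
        RNG seed; identical spec + seed gives a bit-identical table.
    """

    n_regions: int = 116
    n_subjects_per_group: int = 20
    block_sizes: tuple[int, ...] | None = None
    rho_in: float = 0.3
    rho_out: float = 0.1
    hub_region: int | None = None
    rho_hub: float = 0.3
    group_effect: tuple[tuple[int, float], ...] = ()
    group_effect_scope: str = "bridge"

    age_slope: float = -0.003
    sex_offset: float = 0.05
    longitudinal: bool = False
    rho_t: float = 0.8
    followup_change: float | tuple[float, ...] = 0.0
    noise_sd: float = 0.05
    mean_volume: float = 1.0
    age_mean: float = 25.0
    age_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_in", "rho_out", "rho_hub", "rho_t"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise SpecificationError(f"{name}={v} outside (-1, 1)")
        if self.n_regions < 2:
            raise SpecificationError("need at least 2 regions")
        if self.n_subjects_per_group < 2:
            raise SpecificationError("need at least 2 subjects per group")
        if self.noise_sd <= 0:
            raise SpecificationError("noise_sd must be positive")
        if self.block_sizes is not None and sum(self.block_sizes) != self.n_regions:
            raise SpecificationError(
                f"block sizes {self.block_sizes} do not sum to n_regions={self.n_regions}"
            )
        if self.hub_region is not None and not 0 <= self.hub_region < self.n_regions:
            raise SpecificationError(f"hub_region {self.hub_region} out of range")
        for r, _ in self.group_effect:
            if not 0 <= r < self.n_regions:
                raise SpecificationError(f"group_effect region {r} out of range")
        if self.group_effect_scope not in ("bridge", "block", "all"):
            raise SpecificationError(
                f"group_effect_scope must be 'bridge', 'block' or 'all', "
                f"got {self.group_effect_scope!r}"
            )
        # validate both groups' population matrices eagerly
        for group in (0, 1):
            self.population_correlation(group)

    def resolved_block_sizes(self) -> tuple[int, ...]:
        if self.block_sizes is not None:
            return self.block_sizes
        n_full, rem = divmod(self.n_regions, 6)
        sizes = [6] * n_full
        if rem:
            sizes.append(rem)
        return tuple(sizes)

    def population_correlation(self, group: int = 0) -> np.ndarray:
        """Population correlation matrix R for group 0 or 1.

        Raises :class:`SpecificationError` if the implied matrix is not
        positive semi-definite, naming the offending structure.
        """
        n = self.n_regions
        R = np.full((n, n), self.rho_out)
        start = 0
        for size in self.resolved_block_sizes():
            R[start : start + size, start : start + size] = self.rho_in
            start += size
        if self.hub_region is not None:
            R[self.hub_region, :] = self.rho_hub
            R[:, self.hub_region] = self.rho_hub
        np.fill_diagonal(R, 1.0)
        _check_psd(R, "block/hub structure")
        if group == 1 and self.group_effect:
            for r, delta in self.group_effect:
                partners = self._effect_partners(r)
                R[r, partners] += delta
                R[partners, r] += delta
            if np.abs(R[~np.eye(n, dtype=bool)]).max() >= 1.0:
                raise SpecificationError(
                    "group_effect pushes a correlation outside (-1, 1)"
                )
            _check_psd(R, f"group_effect on regions {[r for r, _ in self.group_effect]}")
        return R

    def _blocks(self) -> list[np.ndarray]:
        out, start = [], 0
        for size in self.resolved_block_sizes():
            out.append(np.arange(start, start + size))
            start += size
        return out

    def _effect_partners(self, region: int) -> np.ndarray:
        """Indices whose correlation with ``region`` a group effect shifts."""
        if self.group_effect_scope == "all":
            others = np.arange(self.n_regions)
            return others[others != region]
        blocks = self._blocks()
        own = next(i for i, b in enumerate(blocks) if region in b)
        if self.group_effect_scope == "block":
            members = blocks[own]
            return members[members != region]
        # bridge: first member of each other block, capped at 6 partners
        partners = [int(b[0]) for i, b in enumerate(blocks) if i != own]
        return np.asarray(partners[:6], dtype=int)

    def followup_shift(self) -> np.ndarray:
        shift = np.asarray(self.followup_change, dtype=float)
        if shift.ndim == 0:
            shift = np.full(self.n_regions, float(shift))
        if shift.shape != (self.n_regions,):
            raise SpecificationError("followup_change must be scalar or length n_regions")
        return shift


def _check_psd(R: np.ndarray, what: str) -> None:
    lam_min = np.linalg.eigvalsh(R)[0]
    if lam_min < -_PSD_TOL:
        raise SpecificationError(
            f"population correlation matrix is not positive semi-definite "
            f"(min eigenvalue {lam_min:.3e}); offending structure: {what}"
        )


def implant_group_difference(
    spec: SyntheticSpec, target_region: int, delta_rho: float
) -> SyntheticSpec:
    """Return a spec whose group-2 correlations with ``target_region``
    are shifted by ``delta_rho``.

    The shift follows the spec's ``group_effect_scope``: by default it
    applies to the target's correlations with its covariance-block
    partners (a whole-row shift is PSD-infeasible beyond a handful of
    regions; see :class:`SyntheticSpec`).  The perturbed matrix must
    remain positive semi-definite; otherwise a
    :class:`SpecificationError` is raised (construction validates it).
    A ``delta_rho`` of 0 returns the spec unchanged, keeping the two
    groups exchangeable.
    """
    if delta_rho == 0:
        return spec
    effects = dict(spec.group_effect)
    effects[target_region] = effects.get(target_region, 0.0) + delta_rho
    return replace(spec, group_effect=tuple(sorted(effects.items())))


def region_names_for(n_regions: int) -> list[str]:
    """AAL labels when n_regions == 116, generic ``ROI_###`` otherwise."""
    if n_regions == 116:
        return aal116_labels()
    return [f"ROI_{i + 1:03d}" for i in range(n_regions)]


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a volume table from the spec's generative model.

    Returns a table with ``n_subjects_per_group`` subjects per group
    (each contributing a baseline and a follow-up row when the spec is
    longitudinal).  Sex is allocated 50/50 within each group; ages are
    normal with the spec's mean and SD.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects_per_group
    names = region_names_for(spec.n_regions)
    shift = spec.followup_shift()
    cov_chol = {}
    for g in range(2):
        R = spec.population_correlation(g)
        # eigen-based factor tolerates exactly-singular PSD matrices
        lam, V = np.linalg.eigh(R)
        cov_chol[g] = V * np.sqrt(np.clip(lam, 0.0, None))

    rows = []
    for g, label in enumerate(GROUP_LABELS):
        ages = rng.normal(spec.age_mean, spec.age_sd, size=n)
        sexes = np.zeros(n, dtype=int)
        sexes[: n // 2] = 1
        sexes = rng.permutation(sexes)
        n_draw = 2 if spec.longitudinal else 1
        z = rng.standard_normal((n_draw, n, spec.n_regions))
        eps_bl = z[0] @ cov_chol[g].T * spec.noise_sd
        for s in range(n):
            sid = f"sub-{label[:4]}-{s + 1:03d}"
            base = (
                spec.mean_volume
                + spec.age_slope * (ages[s] - spec.age_mean)
                + spec.sex_offset * (sexes[s] - 0.5)
            )
            rows.append((sid, label, BASELINE, ages[s], sexes[s], base + eps_bl[s]))
            if spec.longitudinal:
                eps_new = z[1, s] @ cov_chol[g].T * spec.noise_sd
                eps_fu = spec.rho_t * eps_bl[s] + np.sqrt(1 - spec.rho_t**2) * eps_new
                fu = base + spec.age_slope * 1.0 + shift + eps_fu
                rows.append((sid, label, FOLLOWUP, ages[s] + 1.0, sexes[s], fu))

    data = {
        "subject_id": [r[0] for r in rows],
        "group": [r[1] for r in rows],
        "timepoint": [r[2] for r in rows],
        "age": [r[3] for r in rows],
        "sex": [r[4] for r in rows],
    }
    vols = np.vstack([r[5] for r in rows])
    if (vols < 0).any():
        warnings.warn(
            "generated volumes fell below 0 and were truncated; "
            "noise_sd is large relative to mean_volume",
            stacklevel=2,
        )
        vols = np.clip(vols, 0.0, None)
    table = pd.concat(
        [pd.DataFrame(data), pd.DataFrame(vols, columns=names)], axis=1
    )
    return table[METADATA_COLUMNS + names]
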