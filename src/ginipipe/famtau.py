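"""Within-family directional Kendall-tau distance statistics for miRNA profiles.

The dissimilarity between two expression profiles over M features is the
Kendall-tau distance d = (1 - tau)/2 with tau the tau-a rank correlation
(tied pairs contribute zero).  Each feature pair (m, m') contributes
(1 - s_mm')/(M(M-1)) to d, where s_mm' is the concordance sign; splitting
every pair's mass equally between its two member features yields a
per-feature decomposition

    c_m = sum_{m' != m} (1 - s_mm') / (2 M (M-1)),   sum_m c_m = d,

so c_m quantifies how much feature m alone drives the patient-vs-healthy
dissimilarity.  Within each sibship the mean pairwise contribution over all
(patient, healthy) pairs is signed by which status group shows the higher
average rank for that feature, and the signed components are summed over
families into an overall directional distance D_m.  Significance is assessed
by permuting affection labels within families only — the exchangeability the
sibling design actually supports — either by Monte-Carlo sampling or by
exact enumeration of all within-family labelings.

Individuals are also clustered on the pairwise tau distance matrix with
Ward's method in its Lance-Williams form applied to raw distances
(the ward.D convention), since a tau distance has no Euclidean embedding.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RankedProfileSet",
    "PairDistance",
    "DirectionalDistanceResult",
    "PermutationResult",
    "ClusterTree",
    "kendall_pair_distance",
    "family_directional_distance",
    "overall_directional_distance",
    "permutation_pvalues",
    "exact_enumeration_pvalues",
    "pairwise_distance_matrix",
    "ward_cluster",
    "filter_expression",
]


@dataclass(frozen=True)
class PairDistance:
    """Kendall tau, the induced [0,1] distance, and its per-feature decomposition."""

    tau: float
    distance: float
    contributions: np.ndarray  # length M, non-negative, sums to distance


@dataclass
class RankedProfileSet:
    """Feature-by-individual expressions with per-profile ranks and sample labels.

    ``values`` is an M x N frame (features x individuals); ``sample_meta``
    has one row per individual with columns ``family_id`` and ``is_patient``.
    Ranks are computed within each individual's profile (average ranks on
    ties), which makes every downstream statistic invariant to strictly
    monotone per-individual transforms of the raw expressions.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    ranks: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if list(self.sample_meta.index) != list(self.values.columns):
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        for fam, sub in self.sample_meta.groupby("family_id"):
            flags = sub["is_patient"].astype(bool)
            if not (flags.any() and (~flags).any()):
                raise ValueError(
                    f"family {fam!r} needs at least one patient and one healthy member"
                )
        self.ranks = self.values.apply(lambda col: rankdata(col.to_numpy()), axis=0)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def families(self) -> list:
        return list(dict.fromkeys(self.sample_meta["family_id"]))

    def family_members(self, family) -> tuple[list, list]:
        sub = self.sample_meta[self.sample_meta["family_id"] == family]
        patients = list(sub.index[sub["is_patient"].astype(bool)])
        healthy = list(sub.index[~sub["is_patient"].astype(bool)])
        return patients, healthy


@dataclass(frozen=True)
class DirectionalDistanceResult:
    feature_ids: list
    families: list
    family_components: pd.DataFrame  # families x features, signed d_fm
    family_signs: pd.DataFrame  # families x features, in {-1, 0, +1}
    overall: pd.Series  # D_m = sum_f d_fm


@dataclass(frozen=True)
class PermutationResult:
    n_permutations: int
    seed: int | None
    observed: pd.Series
    p_up: pd.Series
    p_down: pd.Series
    exact: bool = False

    def report(self) -> pd.DataFrame:
        """Per-feature table sorted by overall directional distance."""
        out = pd.DataFrame(
            {
                "overall_distance": self.observed,
                "p_up": self.p_up,
                "p_down": self.p_down,
            }
        )
        return out.sort_values("overall_distance", ascending=False)


def _pair_signs(x: np.ndarray) -> np.ndarray:
    return np.sign(x[:, None] - x[None, :])


def kendall_pair_distance(x: np.ndarray, y: np.ndarray) -> PairDistance:
    """Tau-a distance between two equal-length profiles with its decomposition.

    ``contributions[m]`` collects half of the discordance mass of every pair
    containing feature m, so the vector is non-negative and sums exactly to
    (1 - tau) / 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    m = x.size
    if m < 2:
        raise ValueError("need at least two features")
    s = _pair_signs(x) * _pair_signs(y)
    np.fill_diagonal(s, 1.0)
    denom = m * (m - 1)
    tau = (s.sum() - m) / denom
    contributions = (1.0 - s).sum(axis=1) / (2.0 * denom)
    return PairDistance(
        tau=float(tau), distance=float((1.0 - tau) / 2.0), contributions=contributions
    )


def _family_pair_contributions(
    profiles: RankedProfileSet, members: list
) -> dict[frozenset, np.ndarray]:
    """Contribution vector of every unordered pair of family members."""
    cols = {s: profiles.values[s].to_numpy() for s in members}
    out = {}
    for a, b in itertools.combinations(members, 2):
        out[frozenset((a, b))] = kendall_pair_distance(cols[a], cols[b]).contributions
    return out


def _signed_component(
    ranks: np.ndarray,
    vals: np.ndarray,
    pair_contrib: dict[frozenset, np.ndarray],
    patients_idx: list[int],
    healthy_idx: list[int],
    members: list,
    sign_mode: str,
) -> np.ndarray:
    """d_fm for one labeling of one family; ranks/vals are M x n_members."""
    pats = [members[i] for i in patients_idx]
    heas = [members[i] for i in healthy_idx]
    base = np.mean(
        [pair_contrib[frozenset((p, h))] for p in pats for h in heas], axis=0
    )
    if sign_mode == "within-profile":
        mean_p = ranks[:, patients_idx].mean(axis=1)
        mean_h = ranks[:, healthy_idx].mean(axis=1)
    elif sign_mode == "per-feature":
        # rank family members within each feature instead of features within profiles
        per_feature = np.apply_along_axis(rankdata, 1, vals)
        mean_p = per_feature[:, patients_idx].mean(axis=1)
        mean_h = per_feature[:, healthy_idx].mean(axis=1)
    else:
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    return np.sign(mean_p - mean_h) * base


def family_directional_distance(
    profiles: RankedProfileSet, family, sign_mode: str = "within-profile"
) -> np.ndarray:
    """Signed per-feature component d_fm for one family.

    The magnitude is the mean tau-distance contribution over all
    (patient, healthy) profile pairs; the sign is +1 where patients show the
    higher average rank for that feature, -1 where the healthy brothers do,
    and 0 on a tie (the family then contributes nothing for that feature).
    """
    patients, healthy = profiles.family_members(family)
    members = patients + healthy
    ranks = profiles.ranks[members].to_numpy()
    vals = profiles.values[members].to_numpy()
    contrib = _family_pair_contributions(profiles, members)
    return _signed_component(
        ranks,
        vals,
        contrib,
        list(range(len(patients))),
        list(range(len(patients), len(members))),
        members,
        sign_mode,
    )


def overall_directional_distance(
    profiles: RankedProfileSet, sign_mode: str = "within-profile"
) -> DirectionalDistanceResult:
    """Sum the signed family components into the overall directional distance D_m."""
    families = profiles.families
    comps = np.vstack(
        [family_directional_distance(profiles, f, sign_mode) for f in families]
    )
    comp_df = pd.DataFrame(comps, index=families, columns=profiles.feature_ids)
    signs = pd.DataFrame(
        np.sign(comps), index=families, columns=profiles.feature_ids
    )
    overall = pd.Series(
        comps.sum(axis=0), index=profiles.feature_ids, name="overall_distance"
    )
    return DirectionalDistanceResult(
        feature_ids=profiles.feature_ids,
        families=families,
        family_components=comp_df,
        family_signs=signs,
        overall=overall,
    )


def _is_one_vs_one(profiles: RankedProfileSet) -> bool:
    for fam in profiles.families:
        p, h = profiles.family_members(fam)
        if len(p) != 1 or len(h) != 1:
            return False
    return True


def _perm_distances_one_vs_one(
    profiles: RankedProfileSet, sign_mode: str, signs: np.ndarray
) -> np.ndarray:
    """D_m for many labelings of an all-sibling-pair design.

    Swapping the two members of a pair leaves the pair contribution unchanged
    and flips the rank-difference sign, so each labeling's statistic is a
    signed sum of the observed family components; ``signs`` is B x F in {-1, +1}.
    """
    comps = np.vstack(
        [family_directional_distance(profiles, f, sign_mode) for f in profiles.families]
    )
    return signs @ comps


def _family_perm_setup(profiles: RankedProfileSet):
    setup = []
    for fam in profiles.families:
        patients, healthy = profiles.family_members(fam)
        members = patients + healthy
        ranks = profiles.ranks[members].to_numpy()
        vals = profiles.values[members].to_numpy()
        contrib = _family_pair_contributions(profiles, members)
        setup.append((members, ranks, vals, contrib, len(patients)))
    return setup


def permutation_pvalues(
    profiles: RankedProfileSet,
    n_permutations: int = 10_000,
    seed: int | None = None,
    sign_mode: str = "within-profile",
) -> PermutationResult:
    """Monte-Carlo p-values from within-family label permutations.

    Each permutation redraws the patient subset of every family uniformly
    among subsets of the observed size, recomputes the overall directional
    distance, and one-sided p-values use the add-one estimator
    p = (1 + #extreme) / (B + 1), which is never zero.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    for fam in profiles.families:
        p, h = profiles.family_members(fam)
        if len(p) + len(h) < 2:  # pragma: no cover - blocked by RankedProfileSet
            warnings.warn(f"family {fam!r} cannot contribute permutation variability")
    rng = np.random.default_rng(seed)
    observed = overall_directional_distance(profiles, sign_mode).overall
    obs = observed.to_numpy()
    b = int(n_permutations)

    if _is_one_vs_one(profiles):
        signs = rng.choice([-1.0, 1.0], size=(b, len(profiles.families)))
        dist = _perm_distances_one_vs_one(profiles, sign_mode, signs)
    else:
        setup = _family_perm_setup(profiles)
        rows = np.empty((b, obs.size))
        for i in range(b):
            total = np.zeros(obs.size)
            for members, ranks, vals, contrib, k in setup:
                idx = rng.permutation(len(members))
                pat, hea = list(idx[:k]), list(idx[k:])
                total += _signed_component(
                    ranks, vals, contrib, pat, hea, members, sign_mode
                )
            rows[i] = total
        dist = rows

    ge = (dist >= obs[None, :] - 1e-12).sum(axis=0)
    le = (dist <= obs[None, :] + 1e-12).sum(axis=0)
    p_up = (1.0 + ge) / (b + 1.0)
    p_down = (1.0 + le) / (b + 1.0)
    return PermutationResult(
        n_permutations=b,
        seed=seed,
        observed=observed,
        p_up=pd.Series(p_up, index=observed.index, name="p_up"),
        p_down=pd.Series(p_down, index=observed.index, name="p_down"),
    )


def exact_enumeration_pvalues(
    profiles: RankedProfileSet,
    sign_mode: str = "within-profile",
    max_labelings: int = 1_000_000,
) -> PermutationResult:
    """Exact one-sided p-values over all within-family labelings.

    The p-value is the proportion of labelings whose statistic is at least
    (at most) the observed one; the identity labeling is included, so p > 0.
    Raises when the labeling count Prod_f C(n_f, k_f) exceeds ``max_labelings``.
    """
    per_family_choices = []
    setup = _family_perm_setup(profiles)
    total_labelings = 1
    for members, ranks, vals, contrib, k in setup:
        combos = list(itertools.combinations(range(len(members)), k))
        total_labelings *= len(combos)
        if total_labelings > max_labelings:
            raise ValueError(
                f"{total_labelings}+ labelings exceed the enumeration bound "
                f"{max_labelings}; use permutation_pvalues instead"
            )
        fam_rows = []
        for pat in combos:
            hea = [i for i in range(len(members)) if i not in pat]
            fam_rows.append(
                _signed_component(
                    ranks, vals, contrib, list(pat), hea, members, sign_mode
                )
            )
        per_family_choices.append(np.vstack(fam_rows))

    observed = overall_directional_distance(profiles, sign_mode).overall
    obs = observed.to_numpy()
    # Fold families in one at a time: running array of labeling sums.
    totals = np.zeros((1, obs.size))
    for fam_rows in per_family_choices:
        totals = (totals[:, None, :] + fam_rows[None, :, :]).reshape(-1, obs.size)
    ge = (totals >= obs[None, :] - 1e-12).sum(axis=0)
    le = (totals <= obs[None, :] + 1e-12).sum(axis=0)
    k = totals.shape[0]
    return PermutationResult(
        n_permutations=k,
        seed=None,
        observed=observed,
        p_up=pd.Series(ge / k, index=observed.index, name="p_up"),
        p_down=pd.Series(le / k, index=observed.index, name="p_down"),
        exact=True,
    )


def pairwise_distance_matrix(profiles: RankedProfileSet) -> pd.DataFrame:
    """Symmetric matrix of tau distances (1 - tau)/2 between all individuals."""
    cols = list(profiles.values.columns)
    n = len(cols)
    mat = np.zeros((n, n))
    arrays = [profiles.values[c].to_numpy() for c in cols]
    for i in range(n):
        for j in range(i + 1, n):
            d = kendall_pair_distance(arrays[i], arrays[j]).distance
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=cols, columns=cols)


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history over individuals.

    ``merges`` rows are (left, right, height, size) with leaves numbered
    0..n-1 and internal nodes n, n+1, ... in merge order, mirroring the
    linkage-matrix convention.
    """

    labels: list
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        n = len(self.labels)
        height_of = {i: 0.0 for i in range(n)}
        node = {i: str(self.labels[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height_of[a], 0.0)
            lb = max(h - height_of[b], 0.0)
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height_of[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def ward_cluster(distance: pd.DataFrame | np.ndarray, labels=None) -> ClusterTree:
    """Agglomerative clustering by Ward's criterion on a precomputed distance.

    Uses the Lance-Williams recurrence on the raw distances (ward.D):
    merging clusters i and j of sizes n_i, n_j updates the distance to any
    cluster k as

        d(ij, k) = ((n_i+n_k) d(i,k) + (n_j+n_k) d(j,k) - n_k d(i,j))
                   / (n_i + n_j + n_k).

    The minimal-distance pair is merged at each step with index-order
    tie-breaking, so the merge history is deterministic.
    """
    if isinstance(distance, pd.DataFrame):
        if labels is None:
            labels = list(distance.index)
        dmat = distance.to_numpy(dtype=float).copy()
    else:
        dmat = np.array(distance, dtype=float)
    n = dmat.shape[0]
    if dmat.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix over >= 2 individuals")
    if labels is None:
        labels = list(range(n))
    active = {i: (i, 1) for i in range(n)}  # slot -> (node id, size)
    dist = {frozenset((i, j)): dmat[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    slots = list(range(n))
    while len(slots) > 1:
        best = None
        for ii in range(len(slots)):
            for jj in range(ii + 1, len(slots)):
                key = frozenset((slots[ii], slots[jj]))
                d = dist[key]
                if best is None or d < best[0] - 1e-15:
                    best = (d, slots[ii], slots[jj])
        h, si, sj = best
        (id_i, n_i), (id_j, n_j) = active[si], active[sj]
        merges.append((id_i, id_j, h, n_i + n_j))
        for sk in slots:
            if sk in (si, sj):
                continue
            n_k = active[sk][1]
            dik = dist[frozenset((si, sk))]
            djk = dist[frozenset((sj, sk))]
            new = ((n_i + n_k) * dik + (n_j + n_k) * djk - n_k * h) / (
                n_i + n_j + n_k
            )
            dist[frozenset((si, sk))] = new
        active[si] = (next_id, n_i + n_j)
        next_id += 1
        slots.remove(sj)
    return ClusterTree(labels=list(labels), merges=np.array(merges, dtype=float))


def filter_expression(
    values: pd.DataFrame,
    detect_floor: float = 0.0,
    min_feature_fraction: float = 0.5,
    min_sample_fraction: float = 0.5,
) -> pd.DataFrame:
    """Drop non-expressed features and low-quality samples.

    A measurement counts as detected when it exceeds ``detect_floor``.
    Features detected in fewer than ``min_feature_fraction`` of samples are
    dropped first; then samples detecting fewer than ``min_sample_fraction``
    of the remaining features are dropped.
    """
    detected = values > detect_floor
    keep_features = detected.mean(axis=1) >= min_feature_fraction
    sub = values.loc[keep_features]
    detected = sub > detect_floor
    keep_samples = detected.mean(axis=0) >= min_sample_fraction
    return sub.loc[:, keep_samples]
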