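"""Seeded generators for every input the analysis stages consume.

The generators emulate the sibling-pair study design: families each
contribute one affected man and one healthy brother (counts configurable),
with per-individual two-color NMD arrays, a miRNA-by-individual expression
matrix with a shared family intercept, miRNA/target sequences with planted
seed sites and site-disrupting variants, and carrier-count tables drawn at a
configured odds ratio.  Every generator is a pure function of its
configuration and seed and returns a planted-truth table sufficient to score
downstream sensitivity and specificity.

Conventions: miRNA sequences use the RNA alphabet (ACGU), genomic targets
use DNA (ACGT).  Two-channel intensities are generated on the linear scale
as lognormal signal plus a known additive background, so background
subtraction is exactly invertible as the noise vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .target_delta import VariantRecord

__all__ = [
    "StudyDesign",
    "NmdSimConfig",
    "MirnaSimConfig",
    "SequenceSimConfig",
    "AssocSimConfig",
    "ArraySample",
    "ExpressionMatrix",
    "simulate_nmd_arrays",
    "simulate_mirna_matrix",
    "simulate_sequences_and_variants",
    "simulate_genotype_tables",
    "simulate_logratio_genes",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sibling-pair sampling design: families of affected men and healthy brothers."""

    n_families: int
    patients_per_family: int = 1
    healthy_per_family: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if self.patients_per_family < 1 or self.healthy_per_family < 1:
            raise ValueError("every family needs at least one member per status")

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for f in range(1, self.n_families + 1):
            fam = f"F{f:02d}"
            for p in range(1, self.patients_per_family + 1):
                rows.append((f"{fam}-P{p}", fam, "affected"))
            for h in range(1, self.healthy_per_family + 1):
                rows.append((f"{fam}-H{h}", fam, "healthy"))
        return pd.DataFrame(rows, columns=["sample_id", "family_id", "status"])


@dataclass(frozen=True)
class NmdSimConfig:
    """Two-color NMD-array generator settings.

    ``n_true_genes`` probes respond to NMD blockade only in affected men
    (the nonsense-transcript signature); ``n_stress_genes`` respond in every
    treated sample (the drug stress response the protocol must exclude).
    """

    n_probes: int = 40_000
    n_true_genes: int = 5
    n_stress_genes: int = 10
    effect_log_ratio: float = 1.0
    noise_sd: float = 0.2
    baseline_intensity: float = 1000.0
    background_level: float = 50.0
    in_region_fraction: float = 0.01  # probes annotated to the Xq27/Xq28 bands

    def __post_init__(self) -> None:
        if self.n_true_genes + self.n_stress_genes > self.n_probes:
            raise ValueError("planted genes exceed probe count")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.baseline_intensity > self.background_level >= 0:
            raise ValueError("need baseline_intensity > background_level >= 0")


@dataclass(frozen=True)
class MirnaSimConfig:
    """miRNA expression generator: planted +/- shifts in patients on a log scale."""

    n_mirnas: int = 333
    n_up: int = 3
    n_down: int = 3
    shift: float = 2.0
    family_sd: float = 0.5
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_mirnas:
            raise ValueError("planted miRNAs exceed total")
        if self.noise_sd <= 0 or self.family_sd < 0:
            raise ValueError("invalid variance components")


@dataclass(frozen=True)
class SequenceSimConfig:
    """Targets with planted perfect-seed miRNA sites and one variant per target."""

    n_targets: int = 40
    window_len: int = 60
    n_mirnas: int = 8
    mirna_len: int = 22
    n_planted_sites: int = 20
    variant_in_site_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.window_len < self.mirna_len:
            raise ValueError("window_len must be >= mirna_len")
        if self.n_planted_sites > self.n_targets:
            raise ValueError("cannot plant more sites than targets")
        if not 0 <= self.variant_in_site_fraction <= 1:
            raise ValueError("variant_in_site_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AssocSimConfig:
    """Carrier-count generator at a configured control frequency and odds ratio."""

    carrier_freq_controls: float = 0.009
    odds_ratio: float = 2.35
    n_cases: int = 757
    n_controls: int = 1896

    def __post_init__(self) -> None:
        if not 0 < self.carrier_freq_controls < 1:
            raise ValueError("control carrier frequency must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        p1 = self.case_carrier_prob
        if not 0 < p1 < 1:
            raise ValueError("implied case carrier probability outside (0, 1)")

    @property
    def case_carrier_prob(self) -> float:
        p0 = self.carrier_freq_controls
        return self.odds_ratio * p0 / (1.0 - p0 + self.odds_ratio * p0)


@dataclass
class ArraySample:
    """One individual's two-color array: treated (r) vs untreated (g) channels."""

    sample_id: str
    family_id: str
    affected: bool
    records: pd.DataFrame  # ProbeName GeneName Band gMeanSignal rMeanSignal g/rBGMedianSignal


@dataclass
class ExpressionMatrix:
    """Features x samples expression with sample and feature annotations."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame


_OFF_REGION_BANDS = ("7q21", "1p36.1", "14q32.2", "17q21.3", "5q31", "20p12")
_REGION_BANDS = ("Xq27.1", "Xq27.2", "Xq27.3", "Xq28")


def simulate_nmd_arrays(
    design: StudyDesign, cfg: NmdSimConfig
) -> tuple[list[ArraySample], pd.DataFrame]:
    """Per-individual two-channel arrays with planted NMD-true and stress genes.

    All planted genes are annotated to the Xq27/Xq28 bands (the screen's
    region of interest), together with a share of null probes; the remaining
    nulls get off-region bands.  Returns the samples and a truth table with
    one row per probe (``class`` in {true, stress, null}).
    """
    rng = np.random.default_rng(design.seed)
    n = cfg.n_probes
    probes = np.array([f"P{i:06d}" for i in range(n)])
    genes = np.array([f"GENE{i:05d}" for i in range(n)])
    classes = np.array(["null"] * n, dtype=object)
    classes[: cfg.n_true_genes] = "true"
    classes[cfg.n_true_genes : cfg.n_true_genes + cfg.n_stress_genes] = "stress"
    n_region = max(int(round(cfg.in_region_fraction * n)), cfg.n_true_genes + cfg.n_stress_genes)
    n_region = min(n_region, n)
    bands = np.empty(n, dtype=object)
    bands[:n_region] = rng.choice(_REGION_BANDS, size=n_region)
    bands[n_region:] = rng.choice(_OFF_REGION_BANDS, size=n - n_region)
    base_log = np.log(cfg.baseline_intensity) + rng.normal(0.0, 0.5, size=n)

    sheet = design.sample_sheet()
    samples = []
    for _, row in sheet.iterrows():
        affected = row["status"] == "affected"
        effect = np.zeros(n)
        effect[classes == "stress"] = cfg.effect_log_ratio
        if affected:
            effect[classes == "true"] = cfg.effect_log_ratio
        g_log = base_log + rng.normal(0.0, cfg.noise_sd, size=n)
        r_log = base_log + effect + rng.normal(0.0, cfg.noise_sd, size=n)
        rec = pd.DataFrame(
            {
                "ProbeName": probes,
                "GeneName": genes,
                "Band": bands,
                "gMeanSignal": np.exp(g_log) + cfg.background_level,
                "rMeanSignal": np.exp(r_log) + cfg.background_level,
                "gBGMedianSignal": np.full(n, cfg.background_level),
                "rBGMedianSignal": np.full(n, cfg.background_level),
            }
        )
        samples.append(
            ArraySample(
                sample_id=row["sample_id"],
                family_id=row["family_id"],
                affected=affected,
                records=rec,
            )
        )
    truth = pd.DataFrame(
        {"probe_id": probes, "gene_id": genes, "band": bands, "class": classes}
    )
    return samples, truth


def simulate_mirna_matrix(
    design: StudyDesign, cfg: MirnaSimConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Log-scale miRNA matrix with family random intercepts and planted shifts.

    Patients carry ``+shift`` on the first ``n_up`` features and ``-shift``
    on the next ``n_down``; every family shares an additive intercept drawn
    with sd ``family_sd`` (brothers are correlated, as the within-family
    permutation analysis assumes).
    """
    rng = np.random.default_rng(design.seed)
    m = cfg.n_mirnas
    features = [f"mir-{i + 1:03d}" for i in range(m)]
    direction = np.array(["null"] * m, dtype=object)
    direction[: cfg.n_up] = "up"
    direction[cfg.n_up : cfg.n_up + cfg.n_down] = "down"
    planted = np.zeros(m)
    planted[direction == "up"] = cfg.shift
    planted[direction == "down"] = -cfg.shift

    sheet = design.sample_sheet()
    # uniform baseline span: a rank statistic saturates for features already at
    # the extremes of the profile, so Gaussian-tail baselines would make the
    # planted shift invisible for a share of features
    baseline = rng.uniform(4.0, 12.0, size=m)
    fam_ids = list(dict.fromkeys(sheet["family_id"]))
    fam_effect = {f: rng.normal(0.0, cfg.family_sd, size=m) for f in fam_ids}
    cols = {}
    for _, row in sheet.iterrows():
        x = baseline + fam_effect[row["family_id"]]
        if row["status"] == "affected":
            x = x + planted
        cols[row["sample_id"]] = x + rng.normal(0.0, cfg.noise_sd, size=m)
    values = pd.DataFrame(cols, index=features)
    meta = sheet.set_index("sample_id")
    feature_meta = pd.DataFrame({"location": [""] * m}, index=features)
    truth = pd.DataFrame({"mirna_id": features, "direction": direction})
    return ExpressionMatrix(values=values, sample_meta=meta, feature_meta=feature_meta), truth


_DNA = np.array(list("ACGT"))
_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_DNA_FROM_RNA = {"A": "A", "C": "C", "G": "G", "U": "T"}
# DNA bases whose transcript neither Watson-Crick- nor wobble-pairs the miRNA base
_BREAKING_DNA = {
    "A": ("C", "G"),  # miRNA A pairs U(T); wobble none besides U:G? A pairs only U
    "C": ("A", "C", "T"),  # miRNA C pairs G only
    "G": ("A", "G"),  # miRNA G pairs C (WC) and T->U (wobble)
    "U": ("C", "T"),  # miRNA U pairs A (WC) and G (wobble)
}


def _revcomp_dna(mirna: str) -> str:
    """DNA reverse complement of a full miRNA (a perfect target site)."""
    rna_rc = "".join(_RNA_COMPLEMENT[b] for b in reversed(mirna))
    return "".join(_DNA_FROM_RNA[b] for b in rna_rc)


def simulate_sequences_and_variants(
    cfg: SequenceSimConfig, seed: int = 0
) -> tuple[dict[str, str], dict[str, str], list[VariantRecord], pd.DataFrame]:
    """Random targets with planted perfect miRNA sites and one variant each.

    A planted site is the exact DNA reverse complement of a full miRNA
    embedded at a random offset (so the wild-type duplex is perfect and in
    particular contains the exact seed complement).  A configured fraction
    of variants falls inside a planted site at a seed-complementary position
    (miRNA positions 2-8), with an allele chosen to break the pairing; the
    rest fall outside every planted site.  Returns (mirnas, targets,
    variants, truth); truth records, per variant, the planted miRNA and
    whether the variant disrupts its site.
    """
    rng = np.random.default_rng(seed)
    mirnas = {
        f"mir-{i + 1:02d}": "".join(
            rng.choice(list("ACGU"), size=cfg.mirna_len)
        )
        for i in range(cfg.n_mirnas)
    }
    mirna_ids = list(mirnas)
    targets: dict[str, str] = {}
    site_info: dict[str, tuple[str, int, int]] = {}  # seq -> (mirna, start, end) 1-based
    for t in range(cfg.n_targets):
        sid = f"tgt{t + 1:03d}"
        seq = "".join(rng.choice(_DNA, size=cfg.window_len))
        if t < cfg.n_planted_sites:
            mid = mirna_ids[int(rng.integers(cfg.n_mirnas))]
            site = _revcomp_dna(mirnas[mid])
            off = int(rng.integers(0, cfg.window_len - len(site) + 1))
            seq = seq[:off] + site + seq[off + len(site) :]
            site_info[sid] = (mid, off + 1, off + len(site))
        targets[sid] = seq

    n_in_site = int(round(cfg.variant_in_site_fraction * cfg.n_targets))
    n_in_site = min(n_in_site, len(site_info))
    in_site_targets = list(site_info)[:n_in_site]
    variants = []
    truth_rows = []
    for sid, seq in targets.items():
        if sid in in_site_targets:
            mid, s1, e1 = site_info[sid]
            L = len(mirnas[mid])
            # site offset k (0-based) pairs miRNA base L-1-k; the seed
            # (miRNA positions 2..8) sits at site offsets L-8 .. L-2
            k0 = int(rng.integers(L - 8, L - 1))
            pos = s1 + k0
            ref = seq[pos - 1]
            mir_base = mirnas[mid][L - 1 - k0]
            choices = [b for b in _BREAKING_DNA[mir_base] if b != ref]
            alt = choices[int(rng.integers(len(choices)))]
            in_site = True
        else:
            forbidden = set()
            if sid in site_info:
                _, s1, e1 = site_info[sid]
                forbidden = set(range(s1, e1 + 1))
            pos = int(rng.integers(1, cfg.window_len + 1))
            while pos in forbidden:
                pos = int(rng.integers(1, cfg.window_len + 1))
            ref = seq[pos - 1]
            alt_choices = [b for b in "ACGT" if b != ref]
            alt = alt_choices[int(rng.integers(3))]
            in_site = False
        variants.append(
            VariantRecord(seq_id=sid, pos=pos, ref=ref, alt=alt, label=f"c.{pos}{ref}>{alt}")
        )
        truth_rows.append(
            {
                "seq_id": sid,
                "pos": pos,
                "in_site": in_site,
                "site_mirna": site_info.get(sid, (None,))[0],
                "site_start": site_info[sid][1] if sid in site_info else -1,
                "site_end": site_info[sid][2] if sid in site_info else -1,
            }
        )
    return mirnas, targets, variants, pd.DataFrame(truth_rows)


def simulate_genotype_tables(cfg: AssocSimConfig, seed: int = 0):
    """Binomial carrier draws plus female genotypes under X-linked HWE.

    Case carrier probability solves the configured odds ratio against the
    control frequency.  Female genotype counts are multinomial at
    Hardy-Weinberg proportions for the control (male hemizygote) allele
    frequency.  Returns (ContingencyTable2x2, XLinkedGenotypeCounts).
    """
    from .association import ContingencyTable2x2, XLinkedGenotypeCounts

    rng = np.random.default_rng(seed)
    a = int(rng.binomial(cfg.n_cases, cfg.case_carrier_prob))
    c = int(rng.binomial(cfg.n_controls, cfg.carrier_freq_controls))
    table = ContingencyTable2x2(
        case_carriers=a,
        case_noncarriers=cfg.n_cases - a,
        control_carriers=c,
        control_noncarriers=cfg.n_controls - c,
    )
    q = cfg.carrier_freq_controls
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    fem = rng.multinomial(cfg.n_controls, probs)
    males = rng.binomial(cfg.n_controls, q)
    counts = XLinkedGenotypeCounts(
        female_AA=int(fem[0]),
        female_Aa=int(fem[1]),
        female_aa=int(fem[2]),
        male_A=int(cfg.n_controls - males),
        male_a=int(males),
    )
    return table, counts


def simulate_logratio_genes(
    n_genes: int,
    n_families: int,
    beta: float = 1.0,
    sd_family: float = 0.5,
    sd_resid: float = 0.2,
    mu: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balanced one-affected/one-healthy log-ratio draws straight from the model.

    Bypasses the array layer: each gene's per-individual value is
    mu + beta * affected + family intercept + noise.  Returns
    (genes x samples values, sample_meta) ready for the mixed-model fitter.
    """
    rng = np.random.default_rng(seed)
    design = StudyDesign(n_families=n_families, seed=0)
    sheet = design.sample_sheet()
    affected = (sheet["status"] == "affected").to_numpy(dtype=float)
    fam_codes = pd.factorize(sheet["family_id"])[0]
    n = len(sheet)
    u = rng.normal(0.0, sd_family, size=(n_genes, n_families))
    e = rng.normal(0.0, sd_resid, size=(n_genes, n))
    vals = mu + beta * affected[None, :] + u[:, fam_codes] + e
    values = pd.DataFrame(
        vals,
        index=[f"GENE{i:04d}" for i in range(n_genes)],
        columns=sheet["sample_id"],
    )
    meta = pd.DataFrame(
        {
            "family_id": sheet["family_id"].to_numpy(),
            "affected": sheet["status"].to_numpy() == "affected",
        },
        index=sheet["sample_id"],
    )
    return values, meta
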