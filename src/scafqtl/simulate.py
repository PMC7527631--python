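"""Synthetic pooled-accession panels with structure, LD and multi-location traits.

The generator emulates the statistical structure the analysis assumes:

* a panel of accessions partitioned into subpopulations whose allele
  frequencies drift from a common ancestral frequency because each
  subpopulation is a finite pool of founder haplotypes: with K founders the
  drift variance is p(1-p)/K, i.e. a Balding-Nichols-style model with
  F = 1/K.  K is chosen per subpopulation as round(1/F) with
  F = 2t/(1+t), which makes the ratio-of-sums Wright FST between two
  equally sized subpopulations match the target t;
* pooled genotypes: each accession is a pool of ``pool_size`` diploids whose
  2*pool_size alleles trace back to ``founder_haplotypes`` haplotypes drawn
  from the accession's subpopulation pool, so its score is an exact allele
  count over 2*pool_size — on the 1/(2*pool_size) grid.  Because drift,
  relatedness and within-accession structure all propagate through the same
  founder haplotypes, linked markers drift together and panel-level LD is
  not attenuated by between-accession variance (the mechanism behind
  long-range correlation in a panel of related cultivars);
* within-scaffold LD through a latent copying chain along each founder
  haplotype: adjacent markers share their latent uniform with probability
  c = exp(-decay_rate * d), so correlation decays with distance d.  A
  fraction pi of founder chains per scaffold are "conserved": they keep a
  single latent across the whole scaffold, putting a distance-independent
  floor under within-scaffold r2; pi is calibrated by quadrature so the
  median far-pair r2 equals the configured floor;
* a minority of long-range correlated marker pairs injected by copying a
  marker's accession founder alleles onto another scaffold with
  per-founder resampling noise;
* multi-location phenotypes: a handful of planted QTLs with prescribed
  explained-variance fractions, a polygenic term drawn with covariance
  proportional to the realized kinship, and location-specific effects
  correlated at a configurable G-by-E level.  Noise is scaled per location
  so the realized broad-sense heritability matches its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import structure
from .types import META_COLUMNS, MarkerPanel, MultiQTLModel, ScaffoldIndex, marker_id


def drift_for_fst(target: float) -> float:
    """Balding-Nichols F giving expected pairwise ratio-of-sums FST = target."""
    if not 0.0 <= target < 1.0:
        raise ValueError(f"FST target {target} outside [0, 1)")
    return 2.0 * target / (1.0 + target)


@dataclass
class TraitConfig:
    """One simulated trait: planted QTLs plus polygenic background."""

    name: str
    n_qtls: int = 5
    qtl_fractions: tuple[float, ...] = (0.12, 0.12, 0.12, 0.12, 0.12)
    h2: float = 0.6
    gxe_correlation: float = 1.0
    polygenic_fraction: float | None = None  # default h2 - sum(qtl_fractions)

    def resolved_polygenic(self) -> float:
        poly = self.polygenic_fraction
        if poly is None:
            poly = self.h2 - sum(self.qtl_fractions[: self.n_qtls])
        if poly < -1e-9:
            raise ValueError(
                f"trait {self.name}: QTL variance fractions exceed heritability"
            )
        return max(poly, 0.0)

    def validate(self) -> None:
        if self.n_qtls > len(self.qtl_fractions):
            raise ValueError(f"trait {self.name}: fewer fractions than QTLs")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"trait {self.name}: h2 outside [0, 1]")
        if not -1.0 <= self.gxe_correlation <= 1.0:
            raise ValueError(f"trait {self.name}: G-by-E correlation outside [-1, 1]")
        total = sum(self.qtl_fractions[: self.n_qtls]) + self.resolved_polygenic()
        if total > 1.0 + 1e-9:
            raise ValueError(f"trait {self.name}: variance fractions sum above 1")


@dataclass
class SimulationConfig:
    """Panel-scale defaults: 150 accessions in 5 subpopulations, 200 scaffolds
    of 25 markers (5,000 markers), 3 locations — the desk-scale analogue of
    the study's 123-accession pooled panel."""

    n_accessions: int = 150
    n_subpops: int = 5
    fst_targets: tuple[float, ...] = (0.02, 0.03, 0.04, 0.05, 0.06)
    n_scaffolds: int = 200
    markers_per_scaffold: int = 25
    scaffold_length_range: tuple[int, int] = (130_000, 600_000)
    # restriction-site loci: markers come in tight clusters (a RAD locus spans
    # a few hundred bp and typically carries several SNPs)
    snps_per_locus: int = 3
    locus_span_bp: int = 300
    decay_rate: float = 8e-6  # per bp; r2 meets the floor near ~150 kbp
    r2_floor: float = 0.1
    long_range_fraction: float = 0.02
    long_range_noise: float = 0.25  # per-haplotype resample probability
    pool_size: int = 8
    # within-accession heterogeneity: a pooled accession is a narrow seed lot
    # whose 2*pool_size alleles trace back to this many founder haplotypes
    founder_haplotypes: int = 6
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    locations: tuple[str, ...] = ("L1", "L2", "L3")
    traits: tuple[TraitConfig, ...] = (TraitConfig(name="T1"),)
    seed: int = 0

    def validate(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.founder_haplotypes < 1:
            raise ValueError("founder_haplotypes must be >= 1")
        if len(self.fst_targets) not in (1, self.n_subpops):
            raise ValueError("fst_targets must be scalar-like or one per subpopulation")
        for t in self.fst_targets:
            drift_for_fst(t)  # validates range
        if not 0.0 <= self.r2_floor < 1.0:
            raise ValueError("r2_floor outside [0, 1)")
        for trait in self.traits:
            trait.validate()

    @property
    def n_markers(self) -> int:
        return self.n_scaffolds * self.markers_per_scaffold

    def subpop_drifts(self) -> np.ndarray:
        targets = self.fst_targets
        if len(targets) == 1:
            targets = targets * self.n_subpops
        return np.array([drift_for_fst(t) for t in targets])


@dataclass
class Truth:
    """Ground truth for recovery scoring: causal markers and effects."""

    causal: dict[str, list[str]] = field(default_factory=dict)  # trait -> marker ids
    effects: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    # trait -> location -> {marker: effect}
    collinear_groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # trait -> causal marker -> panel markers with |r| >= 0.3

    def to_dict(self) -> dict:
        return {
            "causal": self.causal,
            "effects": self.effects,
            "collinear_groups": self.collinear_groups,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Truth":
        return cls(
            causal={k: list(v) for k, v in d["causal"].items()},
            effects=d["effects"],
            collinear_groups=d.get("collinear_groups", {}),
        )


# ---------------------------------------------------------------------------
# genotypes


def _pool_sizes(config: SimulationConfig) -> list[int]:
    """Founder-pool size per subpopulation: K = round(1/F), 0 for no drift."""
    sizes = []
    for F in config.subpop_drifts():
        sizes.append(0 if F == 0.0 else max(int(round(1.0 / F)), 2))
    return sizes


class _GenomeState:
    """Deterministic shared state between the frequency and genotype stages:
    ancestral frequencies, scaffold layout and subpopulation founder pools."""

    def __init__(self, config: SimulationConfig, base_seed: int):
        rng = np.random.default_rng([base_seed, 7])
        m = config.n_markers
        lo, hi = config.ancestral_range
        self.ancestral = rng.uniform(lo, hi, size=m)
        self.scaffolds, self.lengths, self.positions = _scaffold_layout(config, rng)
        self.pool_sizes = _pool_sizes(config)
        kk = sum(self.pool_sizes)
        # one latent-chain pass over all subpop founder haplotypes at once
        self.pool = _chain_alleles(config, rng, kk, self.ancestral, self.positions) if kk else np.empty((0, m), dtype=bool)
        offsets = np.cumsum([0, *self.pool_sizes])
        self.pool_rows = [range(offsets[s], offsets[s + 1]) for s in range(config.n_subpops)]
        self.subpop_freqs = np.vstack(
            [
                self.pool[self.pool_rows[s]].mean(axis=0) if self.pool_sizes[s] else self.ancestral
                for s in range(config.n_subpops)
            ]
        )


def _chain_alleles(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_rows: int,
    freqs: np.ndarray,
    positions: list[np.ndarray],
    conserved_pi: float = 0.0,
) -> np.ndarray:
    """Allele matrix (n_rows x n_markers) from the latent copying chain.

    ``freqs`` is either (n_markers,) or (n_rows, n_markers).  A fraction
    ``conserved_pi`` of row chains keep one latent across each scaffold.
    """
    m = sum(len(p) for p in positions)
    out = np.empty((n_rows, m), dtype=bool)
    freqs2d = freqs if freqs.ndim == 2 else np.broadcast_to(freqs, (1, m))
    col = 0
    for pos in positions:
        conserved = rng.random(n_rows) < conserved_pi
        for j in range(len(pos)):
            if j == 0:
                u = rng.random(n_rows)  # chains restart at each scaffold
            else:
                c = float(np.exp(-config.decay_rate * float(pos[j] - pos[j - 1])))
                refresh = (~conserved) & (rng.random(n_rows) >= c)
                u = np.where(refresh, rng.random(n_rows), u)
            p = freqs2d[:, col] if freqs2d.shape[0] > 1 else freqs2d[0, col]
            out[:, col] = u < p
            col += 1
    return out


def simulate_subpop_frequencies(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-subpopulation allele frequencies for every marker.

    Ancestral frequencies are uniform on ``ancestral_range`` (so QC retains
    most markers); each subpopulation's frequency is the allele fraction of
    its finite founder-haplotype pool, a Balding-Nichols-style drift model
    with F = 1/K.  A zero FST target returns the ancestral frequency exactly
    (no drift).
    """
    config.validate()
    state = _GenomeState(config, config.seed if seed is None else seed)
    return state.ancestral, state.subpop_freqs


def _scaffold_layout(config: SimulationConfig, rng: np.random.Generator):
    """Scaffold names, lengths and sorted marker positions.

    Markers are laid out as restriction-site loci: each locus is a short
    (~``locus_span_bp``) window carrying up to ``snps_per_locus`` SNPs, and
    loci are scattered over the scaffold — the clustered pattern a
    reduced-representation library produces.
    """
    lo, hi = config.scaffold_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_scaffolds)
    scaffolds = [f"scaffold{i + 1}" for i in range(config.n_scaffolds)]
    positions = []
    per_locus = max(config.snps_per_locus, 1)
    span = max(config.locus_span_bp, 1)
    for L in lengths:
        m = config.markers_per_scaffold
        n_loci = -(-m // per_locus)  # ceil
        starts = np.sort(rng.choice(np.arange(1, max(int(L) - span, 2)), size=n_loci, replace=False))
        pos: set[int] = set()
        for s in starts:
            take = min(per_locus, m - len(pos))
            while take > 0:
                cand = int(s + rng.integers(0, span))
                if cand not in pos:
                    pos.add(cand)
                    take -= 1
        positions.append(np.sort(np.fromiter(pos, dtype=int)))
    return scaffolds, lengths, positions


def _conserved_fraction(config: SimulationConfig) -> float:
    """Fraction of scaffold-conserved accession-founder chains hitting the
    configured long-range r2 floor.

    Two markers sharing one latent uniform have Pearson correlation
    rho(p, p') = (min(p, p') - p p') / sqrt(p(1-p) p'(1-p')), so a conserved
    fraction pi gives within-subpopulation score correlation pi * rho.  At
    the panel level this is attenuated by between-subpopulation drift
    variance: corr = pi * rho * v / (v + F_eff), with v the accession
    score-variance factor of the founder-multiplicity pool and F_eff the
    effective drift.  pi solves median(far-pair r2) = r2_floor, the median
    of rho^2 taken by quadrature over the ancestral frequency range.
    Because the conserved chains are idiosyncratic to each accession, the
    floor they create is largely invisible to the accession-level kinship —
    the long-range linkage does not masquerade as population structure.
    """
    if config.r2_floor <= 0:
        return 0.0
    lo, hi = config.ancestral_range
    grid = np.linspace(lo, hi, 101)
    p1, p2 = np.meshgrid(grid, grid)
    rho = (np.minimum(p1, p2) - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    h = 2 * config.pool_size
    k = config.founder_haplotypes
    v = (k - 1 + h) / (h * k)  # E[sum of squared founder weights]
    f_eff = float(np.mean(config.subpop_drifts())) * (1.0 - 1.0 / config.n_subpops)
    w = v / (v + f_eff)
    return float(min(np.sqrt(config.r2_floor / np.median(rho**2)) / w, 1.0))


def simulate_pooled_genotypes(
    subpop_freqs: np.ndarray,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[MarkerPanel, ScaffoldIndex, np.ndarray]:
    """Pooled major-allele-proportion scores with within-scaffold LD.

    Returns ``(panel, scaffold_index, subpop_assignment)``.  Accessions are
    split round-robin over subpopulations.  Scores are exact haplotype-count
    fractions on the 1/(2*pool_size) grid.
    """
    config.validate()
    base = config.seed if seed is None else seed
    state = _GenomeState(config, base)
    rng = np.random.default_rng([base, 8])
    n, m = config.n_accessions, config.n_markers
    h = 2 * config.pool_size
    k = config.founder_haplotypes
    assignment = np.arange(n) % config.n_subpops

    # accession founder alleles (n, k, m): latent chains cut at the accession's
    # subpopulation frequencies.  The frequencies themselves come from finite
    # founder pools (linked markers drift together); the chains' conserved
    # fraction puts the within-scaffold long-range correlation floor into the
    # accessions without creating extra panel-wide structure.
    freqs = np.repeat(subpop_freqs[assignment], k, axis=0)  # (n*k, m)
    alleles = _chain_alleles(
        config, rng, n * k, freqs, state.positions, conserved_pi=_conserved_fraction(config)
    ).reshape(n, k, m)

    # founder multiplicities: how many of the 2*pool_size pooled alleles each
    # founder haplotype contributes (fixed per accession, genome-wide)
    weights = rng.multinomial(h, np.full(k, 1.0 / k), size=n)

    # long-range correlated pairs: noisy founder copies across scaffolds
    n_lr = int(round(config.long_range_fraction * m))
    if n_lr > 0:
        src = rng.choice(m, size=n_lr, replace=False)
        remaining = np.setdiff1d(np.arange(m), src)
        dst = rng.choice(remaining, size=n_lr, replace=False)
        acc_freqs = subpop_freqs[assignment]  # (n, m)
        for s_ix, d_ix in zip(src, dst):
            flip = rng.random((n, k)) < config.long_range_noise
            resample = rng.random((n, k)) < acc_freqs[:, [d_ix]]
            alleles[:, :, d_ix] = np.where(flip, resample, alleles[:, :, s_ix])

    scores = np.einsum("nk,nkm->nm", weights, alleles) / h
    marker_scaffold = [
        scaf for si, scaf in enumerate(state.scaffolds) for _ in state.positions[si]
    ]
    marker_position = [int(p) for pos in state.positions for p in pos]
    scaffolds, lengths = state.scaffolds, state.lengths
    mids = [marker_id(s, p) for s, p in zip(marker_scaffold, marker_position)]
    accessions = [f"acc{i + 1:03d}" for i in range(n)]
    score_df = pd.DataFrame(scores, index=accessions, columns=mids)
    # polarize columns by the panel major allele so scores are major-allele
    # proportions, as the scoring convention requires
    panel_freq = score_df.mean(axis=0)
    flip_cols = panel_freq < 0.5
    score_df.loc[:, flip_cols] = 1.0 - score_df.loc[:, flip_cols]
    nucs = np.array(["A", "C", "G", "T"])
    major = rng.choice(nucs, size=m)
    minor = np.array([rng.choice([x for x in nucs if x != mj]) for mj in major])
    meta = pd.DataFrame(
        {
            "marker_id": mids,
            "scaffold": marker_scaffold,
            "position": marker_position,
            "major_allele": major,
            "minor_allele": minor,
        },
        columns=META_COLUMNS,
    ).set_index("marker_id")
    index = ScaffoldIndex(pd.Series(lengths, index=pd.Index(scaffolds), name="length_bp"))
    return MarkerPanel(score_df, meta), index, assignment


# ---------------------------------------------------------------------------
# phenotypes


def _eligible_markers(panel: MarkerPanel, sd_min: float = 0.1, maf_bounds=(0.02, 0.98)) -> list[str]:
    """Markers whose scores would survive QC (variation + frequency bounds)."""
    scores = panel.scores
    sd = scores.std(axis=0, ddof=1)
    mean = scores.mean(axis=0)
    ok = (sd >= sd_min) & (mean <= maf_bounds[1]) & (1.0 - mean >= maf_bounds[0])
    return list(scores.columns[ok])


def _pick_causal(
    panel: MarkerPanel, n_qtls: int, rng: np.random.Generator, max_r: float = 0.1
) -> list[str]:
    """Random eligible markers on distinct scaffolds, mutually near-orthogonal
    (pairwise |r| below the panel's long-range correlation baseline)."""
    eligible = _eligible_markers(panel)
    rng.shuffle(eligible)
    chosen: list[str] = []
    chosen_scaffolds: set[str] = set()
    X = panel.scores
    for mid in eligible:
        scaf = panel.meta.at[mid, "scaffold"]
        if scaf in chosen_scaffolds:
            continue
        if chosen:
            r = X[chosen].corrwith(X[mid]).abs().max()
            if r >= max_r:
                continue
        chosen.append(mid)
        chosen_scaffolds.add(scaf)
        if len(chosen) == n_qtls:
            return chosen
    raise ValueError(f"could not place {n_qtls} mutually non-collinear QTLs")


def _gxe_draws(rng: np.random.Generator, n_loc: int, rho: float, size: int) -> np.ndarray:
    """(n_loc, size) standard normals with pairwise correlation rho."""
    shared = rng.standard_normal(size)
    if rho >= 1.0:
        return np.tile(shared, (n_loc, 1))
    own = rng.standard_normal((n_loc, size))
    rho = max(rho, 0.0)
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own


def simulate_phenotypes(
    panel: MarkerPanel,
    config: SimulationConfig,
    seed: int | None = None,
    kinship: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, Truth]:
    """Multi-location phenotypes from planted QTLs + polygenic background.

    Per trait and location: y = sum_k beta_k x_k + g + e, with beta chosen so
    each QTL's marginal explained variance matches its configured fraction,
    g drawn with covariance proportional to the realized kinship (trace
    normalized), and e scaled so the realized per-location broad-sense
    heritability equals the target.  When the G-by-E correlation is 1 the
    per-location effect vectors are identical; otherwise effect magnitudes
    are drawn jointly Gaussian across locations at that correlation (matching
    the fractions in expectation).
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    X = panel.values()
    n = panel.n_accessions
    n_loc = len(config.locations)
    if kinship is None:
        kinship = structure.vanraden_kinship(panel).matrix
    K = kinship.to_numpy(dtype=float)
    K = K / max(np.trace(K) / n, 1e-12)  # normalize so diag mean ~ 1
    # chol with jitter for the polygenic draw
    jitter = 1e-8 * np.eye(n)
    L = np.linalg.cholesky(K + jitter)

    records = []
    truth = Truth()
    for trait in config.traits:
        fractions = np.array(trait.qtl_fractions[: trait.n_qtls], dtype=float)
        poly_frac = trait.resolved_polygenic()
        causal = _pick_causal(panel, trait.n_qtls, rng) if trait.n_qtls else []
        truth.causal[trait.name] = causal
        truth.effects[trait.name] = {}
        xc = X[:, [panel.markers.index(c) for c in causal]] if causal else np.zeros((n, 0))
        var_x = xc.var(axis=0, ddof=0) if causal else np.array([])
        base_mag = np.sqrt(fractions / np.clip(var_x, 1e-12, None)) if causal else np.array([])
        signs = rng.choice([-1.0, 1.0], size=len(causal))
        z = _gxe_draws(rng, n_loc, trait.gxe_correlation, len(causal)) if causal else np.zeros((n_loc, 0))
        g_z = _gxe_draws(rng, n_loc, trait.gxe_correlation, n)

        for li, loc in enumerate(config.locations):
            if trait.gxe_correlation >= 1.0:
                beta = base_mag * signs
            else:
                beta = base_mag * z[li]
            genetic = xc @ beta if causal else np.zeros(n)
            if poly_frac > 0:
                g = L @ g_z[li]
                g = g / max(g.std(), 1e-12) * np.sqrt(poly_frac)
                genetic = genetic + g
            var_g = genetic.var()
            if trait.h2 > 0 and var_g > 0:
                var_e = var_g * (1.0 - trait.h2) / trait.h2
            else:
                var_e = 1.0  # pure-noise trait
            e = rng.standard_normal(n) * np.sqrt(var_e)
            y = genetic + e
            truth.effects[trait.name][loc] = {c: float(b) for c, b in zip(causal, beta)}
            records.extend(
                {"accession": acc, "trait": trait.name, "location": loc, "value": float(v)}
                for acc, v in zip(panel.accessions, y)
            )
        if causal:
            groups = {}
            for c in causal:
                r = panel.scores.corrwith(panel.scores[c]).abs()
                groups[c] = list(r.index[r >= 0.3])
            truth.collinear_groups[trait.name] = groups
    phenotypes = pd.DataFrame.from_records(records, columns=["accession", "trait", "location", "value"])
    return phenotypes, truth


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(
    models: list[MultiQTLModel],
    truth: Truth,
    panel: MarkerPanel,
    r_threshold: float = 0.3,
) -> dict:
    """Power and false-discovery proportion of detected QTLs against truth.

    A detected QTL is a true positive iff its representative or any member is
    collinear (|r| >= threshold) with a causal marker of the same trait.
    Power counts causal QTLs matched by at least one detection in at least
    one location's model; FDP is false detections over all detections (0
    when nothing was detected).
    """
    X = panel.scores
    n_causal = 0
    n_detected = 0
    n_false = 0
    causal_hit: dict[tuple[str, str], bool] = {}
    for trait, causal in truth.causal.items():
        for c in causal:
            causal_hit[(trait, c)] = False
        n_causal += len(causal)
    for model in models:
        causal = truth.causal.get(model.trait, [])
        xc = X[causal] if causal else None
        for q in model.qtls:
            n_detected += 1
            members = [q.representative, *q.members]
            matched = False
            if causal:
                with np.errstate(invalid="ignore", divide="ignore"):
                    corr = np.abs(np.corrcoef(
                    X[members].to_numpy(dtype=float).T, xc.to_numpy(dtype=float).T
                )[: len(members), len(members):])
                hits = np.argwhere(corr >= r_threshold)
                for _, ci in hits:
                    causal_hit[(model.trait, causal[ci])] = True
                    matched = True
            if not matched:
                n_false += 1
    power = (sum(causal_hit.values()) / n_causal) if n_causal else float("nan")
    fdp = (n_false / n_detected) if n_detected else 0.0
    return {
        "n_causal": n_causal,
        "n_detected": n_detected,
        "n_true": n_detected - n_false,
        "n_false": n_false,
        "power": power,
        "fdp": fdp,
    }
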