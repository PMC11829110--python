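"""Forward-time simulator of a brood-structured, inbreeding haplodiploid
population with a founder-event invasion.

The life cycle emulates a *Melittobia*-like gregarious parasitoid: each
host patch ("brood") is provisioned by one or a few mated foundresses;
fertilised eggs develop into diploid daughters, unfertilised eggs into
haploid sons; offspring mate within their natal brood (sons are available
to all daughters of the patch); a fraction of mated daughters disperses to
a random other patch, the rest stay to found the next generation at home.
Host patches are ephemeral, and each generation a whole foundress group
can fail to locate a host (``brood_failure_rate``); the patch is then
recolonised from the deme pool.  This patch turnover drives fast matriline
sorting, the engine of the founder-event mitochondrial sweep.
Repeated sib-mating under this cycle drives the strong heterozygote
deficits (F_IS on the order of 0.5–0.8) seen in such wasps.

Genetics:

* microsatellites — unlinked loci under the stepwise mutation model
  (±1 repeat unit with equal probability, rate ``mu_ms`` per gene copy per
  transmission).  SMM deliberately allows homoplasy, the failure mode of
  the private-allele divergence estimator.
* mtDNA — strictly maternal, one sequence per matriline, mutating at rate
  ``mu_mt`` per sequence per transmission at a uniform random site.

At generation ``t_burnin`` the invasive deme is founded by ``n_founders``
mated females drawn from the native deme; both demes then evolve
``t_split`` further generations and are sampled one individual per brood
(mirroring one-individual-per-trap field sampling).

Ground truth: every gene copy carries a flag recording whether any
post-founding mutation occurred on its ancestral copy lineage.  The truth
statistic ``mutated_loci`` reads this flag on a single reference gene copy
(the maternal copy of the first final-generation invasive female), whose
lineage spans exactly ``t_split`` transmissions — the quantity the
divergence estimator models.  The observable counterpart (private alleles
in the sampled data) is computed by :func:`expected_vs_realized_private`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import allele_accounting
from .genotype_io import (
    INVASIVE,
    NATIVE,
    HaplotypeAlignment,
    MicrosatDataset,
    SampleMeta,
)

_BASES = "ACGT"


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Demographic defaults are order-of-magnitude choices for a gregarious
    parasitoid (they are documented design choices, not field estimates);
    mutation parameters default to literature-scale rates: ``mu_ms`` at the
    upper end of the microsatellite bracket, ``mu_mt`` the COI rate
    estimated for the related parasitoid *Nasonia*.
    """

    n_broods: int = 20
    n_broods_native: int | None = 40  # None: same as n_broods
    foundresses_per_brood: int = 4
    brood_size: int = 20
    offspring_sex_ratio: float = 0.8  # proportion female
    disperser_fraction: float = 0.06
    brood_failure_rate: float = 0.0  # whole-patch loss (host not found)
    n_loci: int = 53
    mu_ms: float = 1e-3
    mt_length: int = 532
    mu_mt: float = 7.4e-5
    t_burnin: int = 100
    t_split: int = 600
    n_founders: int = 1
    n_sample: int = 10
    n_sample_native: int | None = 32  # None: same as n_sample
    female_fraction: float = 1.0
    mating: Literal["brood", "random"] = "brood"
    sib_mating_preference: float = 0.9  # P(mate a full brother | available)
    mt_init_haplotypes: int = 3
    init_allele: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "offspring_sex_ratio",
            "disperser_fraction",
            "brood_failure_rate",
            "mu_ms",
            "mu_mt",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.t_split < 1:
            raise ValueError("t_split must be >= 1")
        if self.foundresses_per_brood < 1:
            raise ValueError("foundresses_per_brood must be >= 1")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction outside [0, 1]")


@dataclass
class DemeState:
    """Adults of the current generation of one deme.

    Mated females: genotypes ``G`` (n, loci, 2), stored sperm ``S``
    (n, loci), per-copy post-founding mutation flags ``GM``/``SM``, mtDNA
    ``MT`` (n, mt_length; bases coded 0..3) and the brood each female will
    found.  The brothers of the same generation are kept (``male_*``) so
    mixed-sex samples can be drawn.
    """

    G: np.ndarray
    GM: np.ndarray
    S: np.ndarray
    SM: np.ndarray
    MT: np.ndarray
    brood: np.ndarray
    male_G: np.ndarray
    male_MT: np.ndarray
    male_brood: np.ndarray
    reseed_events: int = 0

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass
class SimTruth:
    t_split: int
    mutated_loci: np.ndarray  # (loci,) bool: reference-lineage indicator
    founder_genotypes: np.ndarray  # (n_founders, loci, 2)
    founder_haplotypes: list[str]
    native_alleles_at_split: list[set[int]]
    homoplasy_count: int
    reseed_events: int


@dataclass
class SimResult:
    config: SimConfig
    native: MicrosatDataset
    invasive: MicrosatDataset
    native_mt: HaplotypeAlignment
    invasive_mt: HaplotypeAlignment
    truth: SimTruth
    final_states: dict[str, DemeState] = field(repr=False, default_factory=dict)

    @property
    def combined(self) -> MicrosatDataset:
        """Both demes as one dataset (shared locus panel)."""
        return MicrosatDataset(
            loci=list(self.native.loci),
            samples=self.native.samples + self.invasive.samples,
            calls={**self.native.calls, **self.invasive.calls},
        )


def _decode_mt(row: np.ndarray) -> str:
    return "".join(_BASES[b] for b in row)


def _init_deme(cfg: SimConfig, rng: np.random.Generator) -> DemeState:
    nf = cfg.n_broods * cfg.foundresses_per_brood
    L = cfg.n_loci
    G = np.full((nf, L, 2), cfg.init_allele, dtype=np.int32)
    S = np.full((nf, L), cfg.init_allele, dtype=np.int32)
    base = rng.integers(0, 4, size=cfg.mt_length).astype(np.uint8)
    haps = [base]
    for h in range(1, max(1, cfg.mt_init_haplotypes)):
        variant = base.copy()
        # second haplotype sits 11 steps away (a distinct "clade"), the
        # rest differ by single steps
        n_diff = 11 if h == 1 else 1
        sites = rng.choice(cfg.mt_length, size=n_diff, replace=False)
        variant[sites] = (variant[sites] + rng.integers(1, 4, size=n_diff)) % 4
        haps.append(variant)
    hap_idx = rng.integers(0, len(haps), size=nf)
    MT = np.stack([haps[i] for i in hap_idx])
    return DemeState(
        G=G,
        GM=np.zeros((nf, L, 2), dtype=bool),
        S=S,
        SM=np.zeros((nf, L), dtype=bool),
        MT=MT,
        brood=np.repeat(np.arange(cfg.n_broods), cfg.foundresses_per_brood),
        male_G=np.empty((0, L), dtype=np.int32),
        male_MT=np.empty((0, cfg.mt_length), dtype=np.uint8),
        male_brood=np.empty(0, dtype=int),
    )


def _mutate_microsat(
    values: np.ndarray,
    flags: np.ndarray,
    active: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    track: bool,
    native_sets: list[set[int]] | None,
) -> int:
    """Apply SMM mutation in place to *values* (n, loci) where *active*;
    returns the number of homoplasic events (new state already present in
    the native allele set at the split)."""
    mask = (rng.random(values.shape) < cfg.mu_ms) & active
    if not mask.any():
        return 0
    steps = rng.integers(0, 2, size=values.shape) * 2 - 1
    values[mask] += steps[mask]
    np.clip(values, 1, None, out=values)  # allele codes stay positive
    if track:
        flags[mask] = True
    homoplasy = 0
    if native_sets is not None:
        for i, j in np.argwhere(mask):
            if int(values[i, j]) in native_sets[j]:
                homoplasy += 1
    return homoplasy


def _step(
    deme: DemeState,
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    track: bool = False,
    native_sets: list[set[int]] | None = None,
) -> tuple[DemeState, int]:
    """Advance one generation; returns (new deme, homoplasy events)."""
    if deme.n == 0:
        raise SimulationError("full-deme extinction: no mated female left")
    nb, bs, L = cfg.n_broods, cfg.brood_size, cfg.n_loci
    reseeds = deme.reseed_events

    # whole-patch failure: hosts are ephemeral and a foundress group can
    # fail to locate one; the patch is then recolonised from the deme pool
    failed = rng.random(nb) < cfg.brood_failure_rate
    alive = ~failed[deme.brood]
    if not alive.any():
        # condition on deme survival (realized invasions are the study
        # object): one random occupied patch escapes the failure sweep
        occupied = np.unique(deme.brood)
        failed[occupied[rng.integers(occupied.size)]] = False
        alive = ~failed[deme.brood]

    # foundress establishment (empty broods reseeded from the deme pool)
    mom = np.empty(nb * bs, dtype=int)
    pool = np.flatnonzero(alive)
    for b in range(nb):
        cand = np.flatnonzero(alive & (deme.brood == b))
        if cand.size == 0:
            reseeds += 1
            cand = pool[rng.integers(0, pool.size, size=1)]
        elif cand.size > cfg.foundresses_per_brood:
            cand = rng.choice(cand, size=cfg.foundresses_per_brood, replace=False)
        mom[b * bs : (b + 1) * bs] = cand[rng.integers(0, cand.size, size=bs)]
    off_brood = np.repeat(np.arange(nb), bs)
    n_off = mom.size
    female = rng.random(n_off) < cfg.offspring_sex_ratio

    # inheritance: one maternal copy (random of the mother's two) for every
    # offspring; daughters additionally receive the stored sperm copy
    which = rng.integers(0, 2, size=(n_off, L))
    mat = np.take_along_axis(deme.G[mom], which[:, :, None], axis=2)[:, :, 0].copy()
    matF = np.take_along_axis(deme.GM[mom], which[:, :, None], axis=2)[:, :, 0].copy()
    pat = deme.S[mom].copy()
    patF = deme.SM[mom].copy()

    homoplasy = _mutate_microsat(
        mat, matF, np.ones_like(mat, dtype=bool), cfg, rng, track, native_sets
    )
    homoplasy += _mutate_microsat(
        pat, patF, np.broadcast_to(female[:, None], pat.shape), cfg, rng, track,
        native_sets,
    )

    # mtDNA: strictly maternal, per-sequence mutation at a random site
    MT = deme.MT[mom].copy()
    for r in np.flatnonzero(rng.random(n_off) < cfg.mu_mt):
        site = int(rng.integers(cfg.mt_length))
        MT[r, site] = (MT[r, site] + rng.integers(1, 4)) % 4

    d_idx = np.flatnonzero(female)
    s_idx = np.flatnonzero(~female)

    # within-brood mating (or deme-wide under the random-mating mode);
    # daughters in broods without sons stay unmated and are dropped
    mated: list[np.ndarray] = []
    husbands: list[np.ndarray] = []
    if cfg.mating == "random":
        if s_idx.size:
            mated.append(d_idx)
            husbands.append(s_idx[rng.integers(0, s_idx.size, size=d_idx.size)])
    else:
        for b in range(nb):
            db = d_idx[off_brood[d_idx] == b]
            sb = s_idx[off_brood[s_idx] == b]
            if db.size and sb.size:
                hb = sb[rng.integers(0, sb.size, size=db.size)]
                if cfg.sib_mating_preference > 0:
                    # kin aggregation at emergence: a daughter mates a full
                    # brother (same mother) when one is present
                    prefer = rng.random(db.size) < cfg.sib_mating_preference
                    son_moms = mom[sb]
                    for m in np.unique(mom[db]):
                        full = sb[son_moms == m]
                        if full.size == 0:
                            continue
                        take = prefer & (mom[db] == m)
                        n_take = int(take.sum())
                        if n_take:
                            hb[take] = full[rng.integers(0, full.size, size=n_take)]
                mated.append(db)
                husbands.append(hb)
    if not mated:
        raise SimulationError("full-deme extinction: no mated female left")
    dd = np.concatenate(mated)
    hh = np.concatenate(husbands)

    natal = off_brood[dd]
    disperse = rng.random(dd.size) < cfg.disperser_fraction
    new_brood = natal.copy()
    if nb > 1 and disperse.any():
        shift = rng.integers(1, nb, size=int(disperse.sum()))
        new_brood[disperse] = (natal[disperse] + shift) % nb

    return (
        DemeState(
            G=np.stack([mat[dd], pat[dd]], axis=2),
            GM=np.stack([matF[dd], patF[dd]], axis=2),
            S=mat[hh],
            SM=matF[hh],
            MT=MT[dd],
            brood=new_brood,
            male_G=mat[s_idx],
            male_MT=MT[s_idx],
            male_brood=off_brood[s_idx],
            reseed_events=reseeds,
        ),
        homoplasy,
    )


def sample_individuals(
    state: DemeState,
    n_per_pop: int,
    female_fraction: float = 1.0,
    rng: np.random.Generator | int = 0,
    population: str = NATIVE,
    group: str | None = None,
    loci: list[str] | None = None,
    id_prefix: str | None = None,
) -> tuple[MicrosatDataset, HaplotypeAlignment]:
    """Draw at most one individual per brood from a deme's final generation.

    ``round(n_per_pop * female_fraction)`` females and the remainder males,
    each from a distinct brood.  Raises when fewer broods carry candidates
    than individuals requested.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    group = group or population
    prefix = id_prefix or population[:3]
    n_f = int(round(n_per_pop * female_fraction))
    n_m = n_per_pop - n_f
    f_broods = sorted(set(state.brood.tolist()))
    m_broods = sorted(set(state.male_brood.tolist()))

    chosen_f: list[int] = []
    chosen_m: list[int] = []
    used: set[int] = set()
    order_f = list(rng.permutation(f_broods)) if f_broods else []
    for b in order_f:
        if len(chosen_f) == n_f:
            break
        idx = np.flatnonzero(state.brood == b)
        chosen_f.append(int(rng.choice(idx)))
        used.add(int(b))
    order_m = [b for b in rng.permutation(m_broods)] if m_broods else []
    for b in order_m:
        if len(chosen_m) == n_m:
            break
        if int(b) in used:
            continue
        idx = np.flatnonzero(state.male_brood == b)
        chosen_m.append(int(rng.choice(idx)))
        used.add(int(b))
    if len(chosen_f) < n_f or len(chosen_m) < n_m:
        raise SimulationError(
            f"not enough distinct broods to sample {n_per_pop} individuals "
            f"({len(chosen_f)}/{n_f} female, {len(chosen_m)}/{n_m} male broods found)"
        )

    L = state.G.shape[1]
    loci = loci or [f"L{k:03d}" for k in range(L)]
    samples: list[SampleMeta] = []
    calls: dict[tuple[str, str], tuple[int, ...] | None] = {}
    ids: list[str] = []
    seqs: list[str] = []
    for i, fi in enumerate(chosen_f):
        sid = f"{prefix}_f{i:02d}"
        samples.append(SampleMeta(sid, population, group, "female"))
        for k, locus in enumerate(loci):
            calls[(sid, locus)] = (int(state.G[fi, k, 0]), int(state.G[fi, k, 1]))
        ids.append(sid)
        seqs.append(_decode_mt(state.MT[fi]))
    for i, mi in enumerate(chosen_m):
        sid = f"{prefix}_m{i:02d}"
        samples.append(SampleMeta(sid, population, group, "male"))
        for k, locus in enumerate(loci):
            calls[(sid, locus)] = (int(state.male_G[mi, k]),)
        ids.append(sid)
        seqs.append(_decode_mt(state.male_MT[mi]))
    dataset = MicrosatDataset(loci=list(loci), samples=samples, calls=calls)
    return dataset, HaplotypeAlignment(ids=ids, seqs=seqs)


def simulate(config: SimConfig) -> SimResult:
    """Run burn-in, founding, post-split evolution and sampling."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # the native deme may be larger than the invasive one: an established
    # region loses little standing variation on the study timescale, while
    # the invasion is a small founder population
    nat_cfg = replace(cfg, n_broods=cfg.n_broods_native or cfg.n_broods)
    native = _init_deme(nat_cfg, rng)
    for _ in range(cfg.t_burnin):
        native, _ = _step(native, nat_cfg, rng)

    # founding of the invasive deme
    if cfg.n_founders > native.n:
        raise SimulationError(
            f"n_founders={cfg.n_founders} exceeds native mated females ({native.n})"
        )
    founder_idx = rng.choice(native.n, size=cfg.n_founders, replace=False)
    native_sets = [
        set(native.G[:, k, :].ravel().tolist()) | set(native.S[:, k].tolist())
        for k in range(cfg.n_loci)
    ]
    invasive = DemeState(
        G=native.G[founder_idx].copy(),
        GM=np.zeros_like(native.GM[founder_idx]),
        S=native.S[founder_idx].copy(),
        SM=np.zeros_like(native.SM[founder_idx]),
        MT=native.MT[founder_idx].copy(),
        brood=np.arange(cfg.n_founders) % cfg.n_broods,
        male_G=np.empty((0, cfg.n_loci), dtype=np.int32),
        male_MT=np.empty((0, cfg.mt_length), dtype=np.uint8),
        male_brood=np.empty(0, dtype=int),
    )
    founder_genotypes = native.G[founder_idx].copy()
    founder_haps = [_decode_mt(native.MT[i]) for i in founder_idx]

    for _ in range(cfg.t_split):
        native, _ = _step(native, nat_cfg, rng)
    homoplasy = 0
    for _ in range(cfg.t_split):
        invasive, h = _step(
            invasive, cfg, rng, track=True, native_sets=native_sets
        )
        homoplasy += h

    loci = [f"L{k:03d}" for k in range(cfg.n_loci)]
    nat_ds, nat_mt = sample_individuals(
        native,
        cfg.n_sample_native or cfg.n_sample,
        cfg.female_fraction,
        rng,
        population=NATIVE,
        loci=loci,
    )
    inv_ds, inv_mt = sample_individuals(
        invasive, cfg.n_sample, cfg.female_fraction, rng, population=INVASIVE, loci=loci
    )
    truth = SimTruth(
        t_split=cfg.t_split,
        mutated_loci=invasive.GM[0, :, 0].copy(),
        founder_genotypes=founder_genotypes,
        founder_haplotypes=founder_haps,
        native_alleles_at_split=native_sets,
        homoplasy_count=homoplasy,
        reseed_events=invasive.reseed_events + native.reseed_events,
    )
    return SimResult(
        config=cfg,
        native=nat_ds,
        invasive=inv_ds,
        native_mt=nat_mt,
        invasive_mt=inv_mt,
        truth=truth,
        final_states={NATIVE: native, INVASIVE: invasive},
    )


def expected_vs_realized_private(result: SimResult) -> tuple[float, float]:
    """(P_any_mutation, P_observable) for one simulation.

    ``P_any_mutation`` — fraction of loci whose reference invasive gene-copy
    lineage carries >= 1 post-founding mutation (the estimator's idealised
    P).  ``P_observable`` — fraction of sampled loci at which the invasive
    sample carries an allele absent from the native sample (what a field
    study can measure; stepwise homoplasy and sampling make it a biased
    version of the former).
    """
    p_any = float(result.truth.mutated_loci.mean())
    inventory = allele_accounting.allele_inventory(result.combined)
    summary = allele_accounting.classify_alleles(
        inventory, focal_pair=(NATIVE, INVASIVE)
    )
    p_obs, _, _ = allele_accounting.locus_private_proportion(
        summary, INVASIVE, basis="amplified"
    )
    return p_any, p_obs


def replicate_configs(base: SimConfig, n_replicates: int) -> list[SimConfig]:
    """Deterministically derived per-replicate configs (seed perturbation)."""
    out = []
    for r in range(n_replicates):
        derived = np.random.SeedSequence([base.seed, r]).generate_state(1, np.uint32)
        out.append(replace(base, seed=int(derived[0]) % (2**31)))
    return out
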