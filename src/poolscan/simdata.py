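"""Forward simulation of the pooled-sequencing study design.

Individuals carry a major biallelic locus that fully determines the
low/heterozygous/complete genotype classes, and a modifier locus that
shifts major-locus heterozygotes between the complete and partial
morphs via a penetrance table.  Individuals are binned into four
phenotype-by-genotype groups, each sequenced as one pool: read depth is
Poisson per site, reads sample chromosomes binomially, and each read
carries the true base with probability 1 - error_rate (else a uniform
other base).

Neutral SNPs near each causal locus are linked to it by an
exponential-decay copying rule: a haplotype at distance d copies the
causal allele state with probability exp(-d/L), otherwise draws from an
independent background frequency.  Background SNPs are unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .poolio import BASES, SiteBlock, write_sync, write_table

MORPHS = ("complete", "partial", "low")
MAJOR_GENOTYPES = ("CC", "CL", "LL")
MODIFIER_GENOTYPES = ("PP", "PC", "CC")
GROUPS = ("Complete_CC", "Low_LL", "Complete_CL", "Partial_CL")
UNASSIGNED = "unassigned"

_DEFAULT_GROUP_SIZES = {"Complete_CC": 74, "Low_LL": 23, "Complete_CL": 42, "Partial_CL": 47}
_DEFAULT_DEPTHS = {"Complete_CC": 65.0, "Low_LL": 71.0, "Complete_CL": 118.0, "Partial_CL": 100.0}
_DEFAULT_PENETRANCE = {"PP": 0.9, "PC": 0.5, "CC": 0.1}
_DEFAULT_PLATE_MEDIANS = {"complete": 47.0, "partial": 39.0, "low": 2.0}


@dataclass
class SimConfig:
    """Parameters of the forward simulation.

    ``group_sizes`` set the four pool sizes (individuals are drawn until
    every group is filled); when None, ``n_individuals`` are drawn once
    and groups take whoever falls into them.  ``ld_length`` is L in the
    copying probability r(d) = exp(-d/L).
    """

    n_individuals: int = 400
    group_sizes: dict[str, int] | None = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_SIZES)
    )
    freq_major_low: float = 0.36
    freq_modifier_partial: float = 0.583
    penetrance: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PENETRANCE))
    plate_medians: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PLATE_MEDIANS)
    )
    n_neutral_snps: int = 2_000
    n_background_snps: int = 48_000
    ld_length: float = 20_000.0
    neutral_span: float | None = None  # placement half-width; default 3 * ld_length
    chrom_name: str = "chrSim"
    chrom_length: int = 1_000_000
    pos_major: int = 250_000
    pos_modifier: int = 750_000
    depth_per_pool: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DEPTHS))
    error_rate: float = 0.003
    background_freq_range: tuple[float, float] = (0.05, 0.95)

    def validate(self) -> None:
        for name, f in (
            ("freq_major_low", self.freq_major_low),
            ("freq_modifier_partial", self.freq_modifier_partial),
        ):
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {f}")
        if set(self.penetrance) != set(MODIFIER_GENOTYPES):
            raise ConfigError(f"penetrance must map exactly {MODIFIER_GENOTYPES}")
        for g, v in self.penetrance.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"penetrance[{g}] must be in [0, 1], got {v}")
        if self.group_sizes is not None:
            unknown = set(self.group_sizes) - set(GROUPS)
            if unknown:
                raise ConfigError(f"unknown groups in group_sizes: {sorted(unknown)}")
            if any(v <= 0 for v in self.group_sizes.values()):
                raise ConfigError("group sizes must be positive")
        for g in GROUPS:
            if self.depth_per_pool.get(g, 0) <= 0:
                raise ConfigError(f"depth_per_pool[{g}] must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        if self.ld_length <= 0:
            raise ConfigError("ld_length must be > 0")
        if self.neutral_span is not None and self.neutral_span <= 0:
            raise ConfigError("neutral_span must be > 0 when set")
        if min(self.n_neutral_snps, self.n_background_snps) < 0:
            raise ConfigError("SNP counts must be non-negative")
        if not (1 <= self.pos_major <= self.chrom_length) or not (
            1 <= self.pos_modifier <= self.chrom_length
        ):
            raise ConfigError("causal positions must lie on the chromosome")
        if self.pos_major == self.pos_modifier:
            raise ConfigError("causal positions must differ")
        lo, hi = self.background_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("background_freq_range must be within [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SimConfig":
        cfg = cls(**dict(d))
        if cfg.group_sizes is not None:
            cfg.group_sizes = {str(k): int(v) for k, v in cfg.group_sizes.items()}
        cfg.background_freq_range = tuple(cfg.background_freq_range)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


@dataclass
class IndividualRecord:
    """One simulated fish."""

    id: int
    major_genotype: str
    modifier_genotype: str
    morph: str
    plate_count: int
    group: str = UNASSIGNED


def assign_group(ind: IndividualRecord) -> str:
    """Map (morph, major genotype) to the study's four pool groups."""
    key = (ind.morph, ind.major_genotype)
    return {
        ("complete", "CC"): "Complete_CC",
        ("low", "LL"): "Low_LL",
        ("complete", "CL"): "Complete_CL",
        ("partial", "CL"): "Partial_CL",
    }.get(key, UNASSIGNED)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _genotypes_from_hwe(freq_allele1: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Number of allele-1 copies (0/1/2) per individual under HWE."""
    return rng.binomial(1, freq_allele1, size=(n, 2)).sum(axis=1)


def simulate_individuals(
    config: SimConfig,
    seed: int | np.random.Generator,
    n: int | None = None,
) -> list[IndividualRecord]:
    """Draw individuals with genotypes at HWE, morphs, and plate counts.

    Major-locus homozygotes are deterministic (LL -> low, CC ->
    complete); heterozygotes are partial with probability
    penetrance[modifier genotype].  Plate counts are decorative Poisson
    draws at morph-specific medians.
    """
    config.validate()
    rng = _as_rng(seed)
    if n is None:
        n = config.n_individuals
    if n < 0:
        raise ConfigError(f"n must be non-negative, got {n}")
    n_low = _genotypes_from_hwe(config.freq_major_low, n, rng)  # copies of L
    n_par = _genotypes_from_hwe(config.freq_modifier_partial, n, rng)  # copies of P
    major = np.array(["CC", "CL", "LL"])[n_low]
    modifier = np.array(["CC", "PC", "PP"])[n_par]
    pen = np.array([config.penetrance[g] for g in modifier])
    u = rng.random(n)
    morph = np.where(
        major == "LL",
        "low",
        np.where(major == "CC", "complete", np.where(u < pen, "partial", "complete")),
    )
    plates = rng.poisson(
        np.array([config.plate_medians[m] for m in morph], dtype=float)
    )
    out = []
    for i in range(n):
        ind = IndividualRecord(
            id=i,
            major_genotype=str(major[i]),
            modifier_genotype=str(modifier[i]),
            morph=str(morph[i]),
            plate_count=int(plates[i]),
        )
        ind.group = assign_group(ind)
        out.append(ind)
    return out


def sample_design_groups(
    config: SimConfig,
    seed: int | np.random.Generator,
    max_draws: int | None = None,
) -> dict[str, list[IndividualRecord]]:
    """Draw individuals until every configured group reaches its target size.

    With ``group_sizes`` unset, a single batch of ``n_individuals`` is
    drawn and groups take whoever lands in them (all must be non-empty).
    """
    config.validate()
    rng = _as_rng(seed)
    if config.group_sizes is None:
        inds = simulate_individuals(config, rng)
        groups = {g: [i for i in inds if i.group == g] for g in GROUPS}
        empty = [g for g, members in groups.items() if not members]
        if empty:
            raise ConfigError(
                f"groups {empty} received no individuals; increase n_individuals "
                "or set group_sizes"
            )
        return groups
    targets = {g: config.group_sizes.get(g, 0) for g in GROUPS}
    if max_draws is None:
        max_draws = 500 * sum(targets.values())
    groups: dict[str, list[IndividualRecord]] = {g: [] for g in GROUPS if targets[g] > 0}
    drawn = 0
    batch = max(200, sum(targets.values()))
    while any(len(groups[g]) < targets[g] for g in groups):
        if drawn >= max_draws:
            raise ConfigError(
                f"could not fill groups {targets} within {max_draws} draws; "
                "check frequencies/penetrance"
            )
        for ind in simulate_individuals(config, rng, n=batch):
            drawn += 1
            g = ind.group
            if g in groups and len(groups[g]) < targets[g]:
                groups[g].append(ind)
    return groups


def individuals_table(groups: Mapping[str, Sequence[IndividualRecord]]) -> pd.DataFrame:
    rows = []
    for g in GROUPS:
        for ind in groups.get(g, []):
            rows.append(
                {
                    "id": ind.id,
                    "group": g,
                    "major_genotype": ind.major_genotype,
                    "modifier_genotype": ind.modifier_genotype,
                    "morph": ind.morph,
                    "plate_count": ind.plate_count,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["id", "group", "major_genotype", "modifier_genotype", "morph", "plate_count"],
    )
    df["id"] = np.arange(len(df))  # re-key across groups
    return df


def morph_percentages(counts: Mapping[str, int]) -> dict[str, int]:
    """Percentage of individuals per morph, rounded to whole percent."""
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("morph counts must sum to a positive total")
    return {m: int(round(100.0 * c / total)) for m, c in counts.items()}


def _genotype_to_haplotypes(
    genotypes: Iterable[str], allele1_hom: str, rng: np.random.Generator
) -> np.ndarray:
    """Phase per-individual genotypes into two 0/1 haplotype states.

    ``allele1_hom`` names the genotype homozygous for allele 1 ("LL" for
    the major locus, "PP" for the modifier); heterozygotes place their
    single allele-1 copy on a random haplotype.
    """
    genotypes = list(genotypes)
    n = len(genotypes)
    hap = np.zeros((n, 2), dtype=bool)
    for i, g in enumerate(genotypes):
        if g == allele1_hom:
            hap[i] = True
        elif g[0] != g[1]:  # heterozygote
            hap[i, rng.integers(0, 2)] = True
    return hap.reshape(-1)


def simulate_pool_counts(
    groups: Mapping[str, Sequence[IndividualRecord]],
    config: SimConfig,
    seed: int | np.random.Generator,
) -> tuple[SiteBlock, pd.DataFrame]:
    """Generate pooled read counts for all sites plus a truth table.

    Returns a :class:`SiteBlock` with one pool per group (ordered as
    ``GROUPS``) and a per-site truth table with true group allele
    frequencies, site kind, and copying probability.
    """
    config.validate()
    rng = _as_rng(seed)
    group_names = [g for g in GROUPS if groups.get(g)]
    if len(group_names) < len([g for g in GROUPS if g in groups]):
        raise ConfigError("empty group passed to simulate_pool_counts")
    if not group_names:
        raise ConfigError("no groups to simulate")
    members = {g: list(groups[g]) for g in group_names}

    # --- haplotypes at the two causal loci, chromosome-major order
    major_hap_parts, modifier_hap_parts, slices = [], [], {}
    offset = 0
    for g in group_names:
        inds = members[g]
        major_hap_parts.append(
            _genotype_to_haplotypes((i.major_genotype for i in inds), "LL", rng)
        )
        modifier_hap_parts.append(
            _genotype_to_haplotypes((i.modifier_genotype for i in inds), "PP", rng)
        )
        slices[g] = slice(offset, offset + 2 * len(inds))
        offset += 2 * len(inds)
    major_hap = np.concatenate(major_hap_parts)
    modifier_hap = np.concatenate(modifier_hap_parts)
    n_chrom = major_hap.size

    # --- site layout
    span = config.neutral_span if config.neutral_span is not None else 3.0 * config.ld_length
    half = config.n_neutral_snps // 2
    neutral_pos_major = config.pos_major + np.rint(
        rng.uniform(-span, span, size=half)
    ).astype(np.int64)
    neutral_pos_mod = config.pos_modifier + np.rint(
        rng.uniform(-span, span, size=config.n_neutral_snps - half)
    ).astype(np.int64)
    background_pos = rng.integers(
        1, config.chrom_length + 1, size=config.n_background_snps, dtype=np.int64
    )
    pos = np.concatenate(
        [
            np.array([config.pos_major, config.pos_modifier], dtype=np.int64),
            neutral_pos_major,
            neutral_pos_mod,
            background_pos,
        ]
    )
    np.clip(pos, 1, config.chrom_length, out=pos)
    kind = np.array(
        ["major", "modifier"]
        + ["neutral"] * config.n_neutral_snps
        + ["background"] * config.n_background_snps,
        dtype=object,
    )
    anchor = np.concatenate(
        [
            np.array([0, 1], dtype=np.int8),
            np.zeros(half, dtype=np.int8),
            np.ones(config.n_neutral_snps - half, dtype=np.int8),
            np.zeros(config.n_background_snps, dtype=np.int8),
        ]
    )
    # de-duplicate positions; causal sites listed first always win
    order = np.lexsort((np.arange(pos.size), pos))
    first = np.zeros(pos.size, dtype=bool)
    sorted_pos = pos[order]
    first[order] = np.concatenate([[True], sorted_pos[1:] != sorted_pos[:-1]])
    first[:2] = True  # keep causal sites
    dup_of_causal = np.zeros(pos.size, dtype=bool)
    dup_of_causal[2:] = np.isin(pos[2:], pos[:2])
    keep_site = first & ~dup_of_causal
    keep_site[:2] = True
    pos, kind, anchor = pos[keep_site], kind[keep_site], anchor[keep_site]
    n_sites = pos.size

    causal_pos = np.array([config.pos_major, config.pos_modifier], dtype=np.int64)
    dist = np.abs(pos - causal_pos[anchor])
    copy_prob = np.where(
        kind == "background", 0.0, np.exp(-dist / config.ld_length)
    )
    copy_prob[kind == "major"] = 1.0
    copy_prob[kind == "modifier"] = 1.0

    lo, hi = config.background_freq_range
    bg_freq = rng.uniform(lo, hi, size=n_sites)

    # --- haplotype allele states (allele 1 = low/partial-linked allele)
    causal_states = np.where(anchor[:, None] == 0, major_hap[None, :], modifier_hap[None, :])
    copy_mask = rng.random((n_sites, n_chrom), dtype=np.float32) < copy_prob[:, None].astype(
        np.float32
    )
    rand_states = rng.random((n_sites, n_chrom), dtype=np.float32) < bg_freq[:, None].astype(
        np.float32
    )
    states = np.where(copy_mask, causal_states, rand_states)
    del copy_mask, rand_states, causal_states

    # --- true per-group allele-1 frequencies
    n_groups = len(group_names)
    true_freq = np.empty((n_sites, n_groups))
    for gi, g in enumerate(group_names):
        true_freq[:, gi] = states[:, slices[g]].mean(axis=1)
    del states

    # --- reads
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    depth_means = np.array([config.depth_per_pool[g] for g in group_names])
    depth = rng.poisson(lam=np.broadcast_to(depth_means, (n_sites, n_groups)))
    alt_reads = rng.binomial(depth, true_freq)
    ref_reads = depth - alt_reads
    counts = np.zeros((n_sites, n_groups, 4), dtype=np.int64)
    s_idx = np.arange(n_sites)[:, None]
    g_idx = np.arange(n_groups)[None, :]
    if config.error_rate > 0:
        err_alt = rng.binomial(alt_reads, config.error_rate)
        err_ref = rng.binomial(ref_reads, config.error_rate)
        alt_reads = alt_reads - err_alt
        ref_reads = ref_reads - err_ref
        third = np.full(3, 1.0 / 3.0)
        spill_alt = rng.multinomial(err_alt, third)  # (S, G, 3)
        spill_ref = rng.multinomial(err_ref, third)
        others_alt = (alt_idx[:, None] + np.arange(1, 4)[None, :]) % 4  # (S, 3)
        others_ref = (ref_idx[:, None] + np.arange(1, 4)[None, :]) % 4
        np.add.at(
            counts,
            (s_idx[:, :, None], g_idx[:, :, None], others_alt[:, None, :]),
            spill_alt,
        )
        np.add.at(
            counts,
            (s_idx[:, :, None], g_idx[:, :, None], others_ref[:, None, :]),
            spill_ref,
        )
    np.add.at(counts, (s_idx, g_idx, ref_idx[:, None]), ref_reads)
    np.add.at(counts, (s_idx, g_idx, alt_idx[:, None]), alt_reads)

    # --- sort by position and package
    order = np.argsort(pos, kind="stable")
    pos, kind, copy_prob, ref_idx, alt_idx = (
        pos[order],
        kind[order],
        copy_prob[order],
        ref_idx[order],
        alt_idx[order],
    )
    true_freq = true_freq[order]
    counts = counts[order]
    base_chars = np.array(list(BASES))
    block = SiteBlock(
        chrom=np.full(n_sites, config.chrom_name, dtype=object),
        pos=pos,
        ref=base_chars[ref_idx].astype("U1"),
        counts=counts,
        dels=np.zeros((n_sites, n_groups), dtype=np.int64),
    )
    truth = pd.DataFrame(
        {
            "chrom": config.chrom_name,
            "pos": pos,
            "ref": base_chars[ref_idx],
            "alt": base_chars[alt_idx],
            "kind": kind,
            "copy_prob": copy_prob,
            **{f"freq_{g}": true_freq[:, gi] for gi, g in enumerate(group_names)},
        }
    )
    return block, truth


def simulate_dataset(
    config: SimConfig,
    seed: int,
    out_prefix: str | Path | None = None,
) -> tuple[SiteBlock, pd.DataFrame, pd.DataFrame]:
    """End-to-end wrapper: groups, pool counts, and optional file output.

    Deterministic given ``seed``.  When ``out_prefix`` is set, writes
    ``<prefix>.sync``, ``<prefix>.truth.tsv`` and
    ``<prefix>.individuals.tsv``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    groups = sample_design_groups(config, rng)
    block, truth = simulate_pool_counts(groups, config, rng)
    inds = individuals_table(groups)
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_sync(block, str(prefix) + ".sync")
        meta = {"seed": seed, "pools": ",".join(g for g in GROUPS if groups.get(g))}
        write_table(truth, str(prefix) + ".truth.tsv", meta)
        write_table(inds, str(prefix) + ".individuals.tsv", meta)
    return block, truth, inds


def expected_partial_fraction(config: SimConfig) -> float:
    """Closed-form P(partial | CL): HWE mixture over modifier genotypes."""
    m = config.freq_modifier_partial
    hwe = {"PP": m * m, "PC": 2 * m * (1 - m), "CC": (1 - m) ** 2}
    return sum(hwe[g] * config.penetrance[g] for g in MODIFIER_GENOTYPES)


def expected_modifier_contrast(config: SimConfig) -> tuple[float, float]:
    """True partial-allele frequency at the modifier SNP, by CL morph class.

    Returns (freq in Partial_CL, freq in Complete_CL): Bayes weights the
    HWE genotype probabilities by penetrance (or its complement) and
    takes the mean allele-1 dose.
    """
    m = config.freq_modifier_partial
    hwe = {"PP": m * m, "PC": 2 * m * (1 - m), "CC": (1 - m) ** 2}
    dose = {"PP": 1.0, "PC": 0.5, "CC": 0.0}
    out = []
    for weight in (config.penetrance, {g: 1 - config.penetrance[g] for g in hwe}):
        w = {g: hwe[g] * weight[g] for g in hwe}
        z = sum(w.values())
        if z == 0:
            out.append(float("nan"))
        else:
            out.append(sum(w[g] * dose[g] for g in hwe) / z)
    return out[0], out[1]
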