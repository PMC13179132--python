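"""Synthetic multi-omics generator with planted ground truth.

Emulates a stage-structured gastruloid-style study design: a small number of
developmental stages sampled in replicate across two or more cell lines, with

* co-regulated protein modules following shared log2 stage profiles,
* anticorrelated module pairs (negated profiles),
* "cooperative" satellite proteins tracking a module's profile at a chosen
  correlation strength,
* per-gene RNA profiles with configurable concordance and planted
  protein-vs-RNA discordance offsets, and
* phosphosites riding on their host protein's profile plus a planted kinase
  activity profile.

All randomness flows through one ``numpy.random.Generator`` (PCG64) seeded
from the config, so identical configs produce bit-identical matrices.  Noise
is Gaussian on the log2 scale; raw matrices are ``2**log2 * base`` with a
random per-gene base abundance.

A note on discordance offsets: the discordance statistic compares fold
changes against each assay's own geometric-mean baseline, so it is invariant
to per-gene constants and any realizable per-gene offset vector sums to zero
across stages.  The generator therefore centres the configured offsets across
stages and records the *realized* (centred) offsets in the ground truth; an
offset vector that already sums to zero is planted exactly as configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceMatrix,
    GeneSet,
    GeneSetCollection,
    PhosphositeMatrix,
    ValidationError,
    make_site_id,
)

DEFAULT_STAGE_NAMES = ("primed", "early", "late")


@dataclass
class ModuleSpec:
    """A planted co-regulated module: all members share ``profile``."""

    name: str
    size: int
    profile: tuple[float, ...]
    sd: float = 0.1  # within-module sd, perturbs each member's stage profile

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValidationError(f"module {self.name!r}: size must be >= 3")
        if self.sd < 0:
            raise ValidationError(f"module {self.name!r}: sd must be >= 0")


@dataclass
class CooperativeSpec:
    """Satellite proteins tracking ``module`` at correlation ``strength``."""

    module: str
    n_satellites: int = 1
    strength: float = 1.0
    sd: float = 0.05


@dataclass
class KinaseSpec:
    """A planted kinase driving ``n_sites`` phosphosites with ``profile``."""

    name: str
    n_sites: int
    profile: tuple[float, ...]
    sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError(f"kinase {self.name!r} must have >= 1 substrate site")


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults emulate the sampling design the package targets: 3 stages x
    3 protein replicates x 2 cell lines, two anticorrelated modules of 10
    proteins with stage profiles spanning 2 log2 units, one fully cooperative
    satellite per module, mild (0.1 log2) within-module and replicate noise,
    fully concordant RNA measured in duplicate, and one active plus one null
    kinase with 10 substrate sites each.
    """

    n_background: int = 50
    modules: list[ModuleSpec] = field(default_factory=lambda: [
        ModuleSpec("module_up", 10, (0.0, 1.0, 2.0), 0.1),
        ModuleSpec("module_down", 10, (0.0, -1.0, -2.0), 0.1),
    ])
    anticorrelated_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("module_up", "module_down")]
    )
    cooperative: list[CooperativeSpec] = field(default_factory=lambda: [
        CooperativeSpec("module_up", 1, 1.0, 0.05),
        CooperativeSpec("module_down", 1, 1.0, 0.05),
    ])
    n_stages: int = 3
    stage_names: tuple[str, ...] = DEFAULT_STAGE_NAMES
    n_replicates: int = 3
    n_rna_replicates: int = 2
    n_groups: int = 2
    replicate_sd: float = 0.1
    # Background stage profiles are kept at an amplitude comparable to the
    # replicate noise floor: with only three stages, two random
    # high-amplitude profiles are frequently near-collinear, and a background
    # gene that coincidentally replicates a module profile is observationally
    # a planted satellite — the labels would no longer be ground truth.  At
    # sd 0.3 (vs 0.1 replicate noise) the attenuation of sample-level r
    # keeps coincidental background pairs below the 0.95 edge gate.
    background_profile_sd: float = 0.3
    # A real proteome-wide network contains many co-regulated groups beyond
    # any one module under test; without them every network edge touches the
    # tested modules and the cooperativity contrast has no power.  Background
    # clusters plant additional co-regulated structure along profile
    # directions 40-140 degrees away from the module axis (in the 2-D centred
    # profile space of a 3-stage design), safely outside the |r| >= 0.95
    # edge cone of the modules and of each other.
    n_background_clusters: int = 6
    background_cluster_size: int = 6
    background_cluster_sd: float = 0.1
    background_cluster_scale: float = 1.0
    # Background singletons are the null class for cooperativity: a singleton
    # whose centred profile happens to point along a module axis would be
    # observationally a planted satellite.  Directions are rejection-sampled
    # outside this angular margin of every configured module axis (the
    # |r| >= 0.95 gate corresponds to an 18.2-degree cone).
    background_min_angle_deg: float = 25.0
    rna_concordance: dict[str, float] | float = 1.0
    rna_sd: float = 0.1
    discordance_offsets: dict[tuple[str, str], float] = field(default_factory=dict)
    phospho: list[KinaseSpec] = field(default_factory=lambda: [
        KinaseSpec("KIN_ACTIVE", 10, (0.0, 1.0, 2.0), 0.1),
        KinaseSpec("KIN_NULL", 10, (0.0, 0.0, 0.0), 0.1),
    ])
    n_background_sites: int = 40
    phospho_site_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages != len(self.stage_names):
            raise ValidationError("stage_names length must equal n_stages")
        for m in self.modules:
            if len(m.profile) != self.n_stages:
                raise ValidationError(
                    f"module {m.name!r}: profile length != n_stages"
                )
        for k in self.phospho:
            if len(k.profile) != self.n_stages:
                raise ValidationError(
                    f"kinase {k.name!r}: profile length != n_stages"
                )
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate module names")
        for a, b in self.anticorrelated_pairs:
            if a not in names or b not in names:
                raise ValidationError(f"anticorrelated pair ({a}, {b}) unknown")
        for c in self.cooperative:
            if c.module not in names:
                raise ValidationError(f"cooperative spec for unknown module {c.module!r}")
        if min(self.replicate_sd, self.rna_sd, self.phospho_site_sd,
               self.background_profile_sd) < 0:
            raise ValidationError("noise sds must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure, recorded exactly as realized in the matrices."""

    module_members: dict[str, list[str]]
    satellites: dict[str, list[str]]
    #: genes x stages realized protein log2 stage profiles (centred per gene)
    gene_profiles: pd.DataFrame
    #: planted background co-regulation clusters (not part of the configured
    #: modules; they exist so the network has structure beyond the modules)
    cluster_members: dict[str, list[str]] = field(default_factory=dict)
    #: genes x stages expected discordance (protein FC - RNA FC)
    discordance: pd.DataFrame | None = None
    #: kinase -> substrate site IDs
    kinase_sites: dict[str, list[str]] = field(default_factory=dict)
    #: kinases x stages planted activity profiles (centred per kinase)
    kinase_profiles: pd.DataFrame | None = None
    concordance: dict[str, float] = field(default_factory=dict)

    def within_module_pairs(self) -> set[frozenset[str]]:
        pairs: set[frozenset[str]] = set()
        for members in self.module_members.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add(frozenset((a, b)))
        return pairs

    def module_gmt(self) -> GeneSetCollection:
        return GeneSetCollection({
            name: GeneSet(name, frozenset(members), "complex")
            for name, members in self.module_members.items()
        })


def _sample_sheet(cfg: SyntheticConfig, assay: str, n_reps: int) -> pd.DataFrame:
    rows = []
    for g in range(1, cfg.n_groups + 1):
        for stage in cfg.stage_names:
            for rep in range(1, n_reps + 1):
                sid = f"{assay}_g{g}_{stage}_r{rep}"
                rows.append({
                    "sample_id": sid,
                    "species": "synthetic",
                    "cell_line": f"line{g}",
                    "stage": stage,
                    "replicate": rep,
                    "assay": assay,
                })
    return pd.DataFrame(rows)


def _expand(stage_profile: np.ndarray, cfg: SyntheticConfig, n_reps: int) -> np.ndarray:
    """Tile a per-stage vector across groups x stages x replicates columns."""
    return np.tile(np.repeat(stage_profile, n_reps), cfg.n_groups)


def _raw(log2_values: np.ndarray, base_log2: np.ndarray) -> np.ndarray:
    return 2.0 ** (log2_values + base_log2[:, None])


def generate_proteome(cfg: SyntheticConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate the raw-scale protein matrix and its ground truth.

    Each module member's log2 profile is the module stage profile plus
    Normal(0, module.sd) per (gene, stage) — shared across replicates and
    groups — plus i.i.d. Normal(0, replicate_sd) per sample.  Background
    genes draw independent stage profiles from Normal(0,
    background_profile_sd).  Cooperative satellites use the module profile
    scaled by their correlation strength plus independent noise.
    """
    rng = np.random.default_rng(cfg.seed)
    sheet = _sample_sheet(cfg, "protein", cfg.n_replicates)
    stage_names = list(cfg.stage_names)

    genes: list[str] = []
    profiles: list[np.ndarray] = []
    module_members: dict[str, list[str]] = {}
    satellites: dict[str, list[str]] = {}

    module_profiles = {m.name: np.asarray(m.profile, float) for m in cfg.modules}
    for m in cfg.modules:
        members = []
        for i in range(m.size):
            gid = f"{m.name}_P{i + 1:02d}"
            prof = module_profiles[m.name] + rng.normal(0.0, m.sd, cfg.n_stages)
            genes.append(gid)
            profiles.append(prof)
            members.append(gid)
        module_members[m.name] = members

    for spec in cfg.cooperative:
        sats = []
        for i in range(spec.n_satellites):
            gid = f"{spec.module}_SAT{i + 1:02d}"
            prof = (spec.strength * module_profiles[spec.module]
                    + rng.normal(0.0, spec.sd, cfg.n_stages))
            genes.append(gid)
            profiles.append(prof)
            sats.append(gid)
        satellites[spec.module] = sats

    cluster_members: dict[str, list[str]] = {}
    if cfg.n_background_clusters:
        if cfg.n_stages < 3:
            raise ValidationError("background clusters need >= 3 stages")
        # orthonormal basis of the centred profile plane: a monotone "up"
        # direction and a quadratic direction orthogonal to it
        s = np.arange(cfg.n_stages, dtype=float)
        u1 = s - s.mean()
        u1 /= np.linalg.norm(u1)
        q = (s - s.mean()) ** 2
        q -= q.mean()
        q -= (q @ u1) * u1
        u2 = q / np.linalg.norm(q)
        amplitude = cfg.background_cluster_scale * np.sqrt(2.0)
        angles = np.linspace(40.0, 140.0, cfg.n_background_clusters)
        for ci, theta in enumerate(np.deg2rad(angles), start=1):
            cname = f"bg_cluster_{ci}"
            base_profile = amplitude * (np.cos(theta) * u1 + np.sin(theta) * u2)
            members = []
            for i in range(cfg.background_cluster_size):
                gid = f"BGC{ci}_P{i + 1:02d}"
                prof = base_profile + rng.normal(
                    0.0, cfg.background_cluster_sd, cfg.n_stages)
                genes.append(gid)
                profiles.append(prof)
                members.append(gid)
            cluster_members[cname] = members

    module_axes = []
    for prof in module_profiles.values():
        axis = np.asarray(prof, float) - np.mean(prof)
        norm = np.linalg.norm(axis)
        if norm > 0:
            module_axes.append(axis / norm)
    max_cos = np.cos(np.deg2rad(cfg.background_min_angle_deg))

    def _background_profile() -> np.ndarray:
        for _ in range(1000):
            prof = rng.normal(0.0, cfg.background_profile_sd, cfg.n_stages)
            centred = prof - prof.mean()
            norm = np.linalg.norm(centred)
            if norm == 0:
                return prof
            if all(abs(centred @ ax) / norm <= max_cos for ax in module_axes):
                return prof
        raise ValidationError(
            "could not sample a background profile outside the module cones"
        )

    for i in range(cfg.n_background):
        gid = f"BG_P{i + 1:03d}"
        genes.append(gid)
        profiles.append(_background_profile())

    if len(genes) != len(set(genes)):
        raise ValidationError("generated feature IDs collide")

    prof_arr = np.vstack(profiles)
    n_cols = cfg.n_groups * cfg.n_stages * cfg.n_replicates
    log2 = np.vstack([_expand(p, cfg, cfg.n_replicates) for p in prof_arr])
    log2 = log2 + rng.normal(0.0, cfg.replicate_sd, (len(genes), n_cols))
    base = rng.uniform(10.0, 20.0, len(genes))  # per-gene base abundance, log2 scale
    values = pd.DataFrame(_raw(log2, base), index=genes,
                          columns=sheet["sample_id"].tolist())

    centred = prof_arr - prof_arr.mean(axis=1, keepdims=True)
    truth = GroundTruth(
        module_members=module_members,
        satellites=satellites,
        gene_profiles=pd.DataFrame(centred, index=genes, columns=stage_names),
        cluster_members=cluster_members,
    )
    matrix = AbundanceMatrix(values, sheet, scale="raw")
    return matrix, truth


def generate_transcriptome(
    cfg: SyntheticConfig, truth: GroundTruth
) -> AbundanceMatrix:
    """Generate the raw-scale RNA matrix matched to an existing proteome.

    Per gene, the RNA log2 stage profile is ``concordance * protein profile -
    offset`` plus per-sample noise, where the offsets are the configured
    discordance offsets centred across stages (see module docstring).  The
    expected realized discordance ``protein FC - RNA FC`` is recorded in
    ``truth.discordance``.  RNA uses ``n_rna_replicates`` (default 2)
    replicates per condition, fewer than the proteome, so downstream
    operations must handle unbalanced replication.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    sheet = _sample_sheet(cfg, "rna", cfg.n_rna_replicates)
    stage_names = list(cfg.stage_names)
    genes = list(truth.gene_profiles.index)

    conc = cfg.rna_concordance
    conc_map = {g: (conc.get(g, 1.0) if isinstance(conc, dict) else float(conc))
                for g in genes}
    offsets = np.zeros((len(genes), cfg.n_stages))
    for (gene, stage), off in cfg.discordance_offsets.items():
        if gene not in truth.gene_profiles.index:
            raise ValidationError(f"discordance offset for unknown gene {gene!r}")
        if stage not in stage_names:
            raise ValidationError(f"discordance offset for unknown stage {stage!r}")
        offsets[genes.index(gene), stage_names.index(stage)] = off
    offsets = offsets - offsets.mean(axis=1, keepdims=True)  # realizable part

    prot = truth.gene_profiles.to_numpy()
    c = np.array([conc_map[g] for g in genes])[:, None]
    rna_profiles = c * prot - offsets
    expected_d = prot - (rna_profiles - rna_profiles.mean(axis=1, keepdims=True))

    n_cols = cfg.n_groups * cfg.n_stages * cfg.n_rna_replicates
    log2 = np.vstack([_expand(p, cfg, cfg.n_rna_replicates) for p in rna_profiles])
    log2 = log2 + rng.normal(0.0, cfg.rna_sd, (len(genes), n_cols))
    base = rng.uniform(4.0, 12.0, len(genes))
    values = pd.DataFrame(_raw(log2, base), index=genes,
                          columns=sheet["sample_id"].tolist())

    truth.discordance = pd.DataFrame(expected_d, index=genes, columns=stage_names)
    truth.concordance = conc_map
    return AbundanceMatrix(values, sheet, scale="raw")


def generate_phosphoproteome(
    cfg: SyntheticConfig, truth: GroundTruth
) -> tuple[PhosphositeMatrix, GroundTruth]:
    """Generate log2-ratio phosphosites matched to an existing proteome.

    Each site's log2 profile is its host protein's realized stage profile
    plus the owning kinase's activity profile (zero for background sites)
    plus i.i.d. noise.  Hosts are drawn without replacement per kinase from
    the proteome's genes; residue and position are arbitrary but unique.
    Returns the site matrix (same sample layout as the proteome) and the
    updated ground truth with the kinase->site map and activity profiles.
    """
    for k in cfg.phospho:
        if k.n_sites < 1:
            raise ValidationError(f"kinase {k.name!r} has no substrate sites")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    sheet = _sample_sheet(cfg, "phosphosite", cfg.n_replicates)
    stage_names = list(cfg.stage_names)
    genes = list(truth.gene_profiles.index)
    residues = np.array(["S", "T", "Y"])

    site_ids: list[str] = []
    site_rows: list[dict] = []
    site_profiles: list[np.ndarray] = []
    kinase_sites: dict[str, list[str]] = {}
    used_positions: set[tuple[str, str, int]] = set()

    def _new_site(host: str) -> tuple[str, str, int]:
        while True:
            res = str(rng.choice(residues, p=[0.7, 0.25, 0.05]))
            pos = int(rng.integers(1, 2000))
            if (host, res, pos) not in used_positions:
                used_positions.add((host, res, pos))
                return host, res, pos

    specs: list[tuple[str | None, int, np.ndarray, float]] = [
        (k.name, k.n_sites, np.asarray(k.profile, float), k.sd) for k in cfg.phospho
    ]
    specs.append((None, cfg.n_background_sites,
                  np.zeros(cfg.n_stages), cfg.phospho_site_sd))

    for kname, n_sites, activity, sd in specs:
        ids = []
        for _ in range(n_sites):
            host = genes[int(rng.integers(len(genes)))]
            host, res, pos = _new_site(host)
            sid = make_site_id(host, res, pos)
            host_prof = truth.gene_profiles.loc[host].to_numpy()
            prof = host_prof + activity + rng.normal(0.0, sd, cfg.n_stages)
            site_ids.append(sid)
            site_rows.append({"protein": host, "residue": res, "position": pos})
            site_profiles.append(prof)
            ids.append(sid)
        if kname is not None:
            kinase_sites[kname] = ids

    n_cols = cfg.n_groups * cfg.n_stages * cfg.n_replicates
    log2 = np.vstack([_expand(p, cfg, cfg.n_replicates) for p in site_profiles])
    log2 = log2 + rng.normal(0.0, cfg.phospho_site_sd, (len(site_ids), n_cols))
    values = pd.DataFrame(log2, index=site_ids, columns=sheet["sample_id"].tolist())
    sites = pd.DataFrame(site_rows, index=site_ids)

    truth.kinase_sites = kinase_sites
    kin_prof = np.array([np.asarray(k.profile, float) for k in cfg.phospho])
    truth.kinase_profiles = pd.DataFrame(
        kin_prof - kin_prof.mean(axis=1, keepdims=True),
        index=[k.name for k in cfg.phospho], columns=stage_names,
    )
    matrix = PhosphositeMatrix(values, sheet, sites, scale="log2_ratio")
    return matrix, truth


def kinase_substrate_table(truth: GroundTruth) -> pd.DataFrame:
    """The planted kinase->substrate map in the standard table layout."""
    from .datatypes import parse_site_id

    rows = []
    for kinase, sids in truth.kinase_sites.items():
        for sid in sids:
            protein, residue, position = parse_site_id(sid)
            rows.append({"kinase": kinase, "substrate": protein,
                         "residue": residue, "position": position})
    return pd.DataFrame(rows, columns=["kinase", "substrate", "residue", "position"])
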