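"""Synthetic storage-experiment generator with known ground truth.

Emulates the post-mapping count tables of a biospecimen storage experiment:
four sample matrices (two pig feces, P1/P2; two sewage, S1/S2), each stored
at four temperatures (−80, −20, 5, 22 °C) for 16 h or 64 h plus an
unstored 0 h reference, in triplicate, with spiked and unspiked duplicates
and a freeze-thaw-cycle series for P1 and S1.  Storage shifts taxon
abundances on the log2 scale per phylum: storage above freezing favors
Firmicutes and Actinobacteria and depletes Bacteroidetes and Proteobacteria;
frozen storage does the opposite (both frozen temperatures share one effect
vector, as frozen samples behave alike); freeze-thaw cycles favor
eukaryotes, Firmicutes and Actinobacteria per cycle.  Counts are drawn
gamma-Poisson (negative binomial) around the expected profile, a linked
antimicrobial-resistance gene table is derived from per-gene host taxa, and
an 8-member mock community can be spiked on top of the native means.  Every
planted quantity is recorded in a :class:`GroundTruth` object so downstream
analyses can be scored against it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "EffectModel",
    "MockMember",
    "MockSpec",
    "Condition",
    "GroundTruth",
    "SimulatedDataset",
    "default_effect_model",
    "default_mock_spec",
    "simulate_baseline",
    "apply_storage_effect",
    "sample_counts",
    "spike_mock",
    "simulate_amr",
    "generate_dataset",
]

FROZEN_TEMPS = (-80, -20)
WARM_FAVORED = ("Firmicutes", "Actinobacteria")
COLD_FAVORED = ("Bacteroidetes", "Proteobacteria")
EUKARYOTE_PHYLA = ("Apicomplexa", "Ascomycota")
BACTERIAL_PHYLA = (
    "Firmicutes",
    "Actinobacteria",
    "Bacteroidetes",
    "Proteobacteria",
    "Spirochaetes",
    "Fusobacteria",
)
ALL_PHYLA = BACTERIAL_PHYLA + ("Euryarchaeota",) + EUKARYOTE_PHYLA
# sampling weights for assigning genera to phyla (gut/sewage-like mix)
_PHYLUM_WEIGHTS = {
    "Firmicutes": 0.30,
    "Bacteroidetes": 0.22,
    "Proteobacteria": 0.18,
    "Actinobacteria": 0.12,
    "Spirochaetes": 0.06,
    "Fusobacteria": 0.04,
    "Euryarchaeota": 0.04,
    "Apicomplexa": 0.02,
    "Ascomycota": 0.02,
}

AMR_CLASSES = (
    "tetracycline",
    "macrolide",
    "beta-lactam",
    "aminoglycoside",
    "lincosamide",
    "sulfonamide",
)
# per-phylum class preferences so resistome composition tracks taxonomy
_CLASS_WEIGHTS_BY_PHYLUM = {
    "Firmicutes": (0.40, 0.25, 0.05, 0.10, 0.15, 0.05),
    "Actinobacteria": (0.30, 0.25, 0.10, 0.15, 0.15, 0.05),
    "Bacteroidetes": (0.35, 0.15, 0.30, 0.10, 0.05, 0.05),
    "Proteobacteria": (0.10, 0.20, 0.35, 0.20, 0.02, 0.13),
    "Spirochaetes": (0.40, 0.20, 0.10, 0.15, 0.10, 0.05),
    "Fusobacteria": (0.30, 0.25, 0.20, 0.10, 0.10, 0.05),
    "Euryarchaeota": (0.20, 0.20, 0.20, 0.20, 0.10, 0.10),
}


@dataclass(frozen=True)
class Condition:
    """A storage condition: temperature × time, or a freeze-thaw cycle count."""

    time_h: float
    temperature_c: float | None = None  # None only at 0 h
    freeze_thaw_cycles: int = 0

    def __post_init__(self):
        if self.time_h == 0 and self.temperature_c is not None:
            raise ValueError("the 0 h condition carries no storage temperature")
        if self.time_h > 0 and self.temperature_c is None:
            raise ValueError("stored samples need a temperature")
        if self.freeze_thaw_cycles and self.temperature_c not in FROZEN_TEMPS:
            raise ValueError(
                f"freeze-thaw cycles require a frozen temperature, got "
                f"{self.temperature_c} °C"
            )

    @property
    def label(self) -> str:
        if self.time_h == 0:
            return "0h"
        if self.freeze_thaw_cycles:
            return f"FT{self.freeze_thaw_cycles}_{self.temperature_c:g}C"
        return f"{self.time_h:g}h_{self.temperature_c:g}C"


@dataclass(frozen=True)
class DesignSpec:
    """The experimental design enumerated by :func:`generate_dataset`."""

    matrices: tuple = ("P1", "P2", "S1", "S2")
    temperatures: tuple = (-80, -20, 5, 22)
    times_h: tuple = (0, 16, 64)
    replicates: int = 3
    freeze_thaw_cycles: tuple = (2, 3, 4)
    freeze_thaw_temps: tuple = (-80, -20)
    freeze_thaw_matrices: tuple = ("P1", "S1")
    freeze_thaw_time_h: dict = field(
        default_factory=lambda: {2: 40, 3: 64, 4: 88}
    )
    spiked_states: tuple = (False, True)
    n_genera: int = 200
    n_amr_genes: int = 150
    library_size: float = 2e5

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if 0 not in self.times_h:
            raise ValueError("the design must include the 0 h reference")
        if sum(t == 0 for t in self.times_h) != 1:
            raise ValueError("time 0 must appear exactly once")
        if self.n_genera < 20:
            raise ValueError("n_genera must be >= 20")
        bad = set(self.freeze_thaw_temps) - set(FROZEN_TEMPS)
        if bad:
            raise ValueError(f"freeze-thaw cycles at non-frozen temperature(s): {bad}")
        if not set(self.freeze_thaw_matrices) <= set(self.matrices):
            raise ValueError("freeze-thaw matrices must be design matrices")

    def conditions(self, matrix: str) -> list[Condition]:
        conds = [Condition(time_h=0)]
        for temp in self.temperatures:
            for t in self.times_h:
                if t > 0:
                    conds.append(Condition(time_h=t, temperature_c=temp))
        if matrix in self.freeze_thaw_matrices:
            for temp in self.freeze_thaw_temps:
                for cyc in self.freeze_thaw_cycles:
                    conds.append(
                        Condition(
                            time_h=self.freeze_thaw_time_h[cyc],
                            temperature_c=temp,
                            freeze_thaw_cycles=cyc,
                        )
                    )
        return conds


@dataclass(frozen=True)
class EffectModel:
    """Planted storage effects, in log2 fold change per unit scaled time.

    ``phylum_effects[temp][phylum]`` is the log2 shift a taxon of that
    phylum accrues over the full 0–64 h span at that temperature; hours are
    mapped linearly onto [0, 1].  ``freeze_thaw_effects[phylum]`` is a log2
    slope per freeze-thaw cycle.  ``taxon_effect_sd`` disperses individual
    taxa around their phylum effect; ``nb_dispersion`` is the gamma-Poisson
    dispersion of replicate counts; ``library_size_lognormal_sd`` scales
    sequencing-depth variation.
    """

    phylum_effects: dict
    freeze_thaw_effects: dict
    taxon_effect_sd: float = 0.2
    nb_dispersion: float = 0.05
    library_size_lognormal_sd: float = 0.3
    time_scale_h: float = 64.0

    def __post_init__(self):
        for temp, eff in self.phylum_effects.items():
            warm = temp not in FROZEN_TEMPS
            for ph in WARM_FAVORED:
                v = eff.get(ph, 0.0)
                if (warm and v < 0) or (not warm and v > 0):
                    raise ValueError(
                        f"{ph} effect at {temp} °C has the wrong sign ({v})"
                    )
            for ph in COLD_FAVORED:
                v = eff.get(ph, 0.0)
                if (warm and v > 0) or (not warm and v < 0):
                    raise ValueError(
                        f"{ph} effect at {temp} °C has the wrong sign ({v})"
                    )
        for ph in EUKARYOTE_PHYLA + WARM_FAVORED:
            if self.freeze_thaw_effects.get(ph, 0.0) < 0:
                raise ValueError(f"freeze-thaw slope for {ph} must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def rate(self, temperature_c: float, phylum: str) -> float:
        if temperature_c not in self.phylum_effects:
            raise ValueError(f"unknown storage temperature {temperature_c} °C")
        return self.phylum_effects[temperature_c].get(phylum, 0.0)


def default_effect_model() -> EffectModel:
    """Default planted effects, calibrated to the qualitative ordering only:
    22 °C/64 h moves farthest from baseline, 5 °C is milder, and the two
    frozen temperatures share one (sign-flipped, intermediate) effect.
    """
    frozen = {
        "Firmicutes": -0.7,
        "Actinobacteria": -0.6,
        "Bacteroidetes": 0.7,
        "Proteobacteria": 0.6,
    }
    return EffectModel(
        phylum_effects={
            -80: dict(frozen),
            -20: dict(frozen),
            5: {
                "Firmicutes": 0.6,
                "Actinobacteria": 0.5,
                "Bacteroidetes": -0.6,
                "Proteobacteria": -0.5,
            },
            22: {
                "Firmicutes": 1.2,
                "Actinobacteria": 1.0,
                "Bacteroidetes": -1.2,
                "Proteobacteria": -1.0,
            },
        },
        freeze_thaw_effects={
            "Apicomplexa": 0.5,
            "Ascomycota": 0.5,
            "Firmicutes": 0.3,
            "Actinobacteria": 0.3,
            "Bacteroidetes": -0.3,
            "Proteobacteria": -0.3,
        },
    )


@dataclass(frozen=True)
class MockMember:
    genus: str
    phylum: str
    cell_class: str  # gram_positive | gram_negative | eukaryote
    genome_size_bp: float
    cells_per_mg: float
    extraction_efficiency: float

    def __post_init__(self):
        if self.cells_per_mg <= 0:
            raise ValueError(f"{self.genus}: cells_per_mg must be positive")
        if self.genome_size_bp <= 0:
            raise ValueError(f"{self.genus}: genome size must be positive")


@dataclass(frozen=True)
class MockSpec:
    """The 8-member spike-in mock community and its spiking level."""

    members: tuple
    spike_fraction: float = 0.05

    def __post_init__(self):
        if len(self.members) != 8:
            raise ValueError("the mock community has exactly 8 members")
        classes = {m.cell_class for m in self.members}
        if "eukaryote" not in classes or not classes & {"gram_positive", "gram_negative"}:
            raise ValueError("mock community must span bacteria and eukaryotes")

    @property
    def genera(self) -> tuple:
        return tuple(m.genus for m in self.members)


# extraction efficiencies mimic higher DNA yield from Gram-negative cells
_EFFICIENCY = {"gram_negative": 1.0, "gram_positive": 0.3, "eukaryote": 0.1}
_MOCK_TEMPLATE = (
    # genus, phylum, class, genome bp
    ("Propionibacterium", "Actinobacteria", "gram_positive", 2.6e6),
    ("Staphylococcus", "Firmicutes", "gram_positive", 2.8e6),
    ("Bacteroides", "Bacteroidetes", "gram_negative", 5.2e6),
    ("Fusobacterium", "Fusobacteria", "gram_negative", 2.2e6),
    ("Escherichia", "Proteobacteria", "gram_negative", 4.6e6),
    ("Salmonella", "Proteobacteria", "gram_negative", 4.9e6),
    ("Saccharomyces", "Ascomycota", "eukaryote", 1.2e7),
    ("Cryptosporidium", "Apicomplexa", "eukaryote", 9.1e6),
)


def default_mock_spec(matrix: str = "P2", spike_fraction: float = 0.05) -> MockSpec:
    """Mock community at 1e9 cells/mg Gram-positive (5e8 for matrix P1),
    1e8 cells/mg Gram-negative, 2e7 cells/mg yeast and 2e6 cells/mg
    Cryptosporidium oocysts."""
    gram_pos = 5e8 if matrix == "P1" else 1e9
    cells = {"gram_positive": gram_pos, "gram_negative": 1e8}
    per_genus = {"Saccharomyces": 2e7, "Cryptosporidium": 2e6}
    members = tuple(
        MockMember(
            genus=g,
            phylum=ph,
            cell_class=cls,
            genome_size_bp=size,
            cells_per_mg=per_genus.get(g, cells.get(cls)),
            extraction_efficiency=_EFFICIENCY[cls],
        )
        for g, ph, cls, size in _MOCK_TEMPLATE
    )
    return MockSpec(members=members, spike_fraction=spike_fraction)


def _stable_offset(tag: str) -> int:
    return int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")


def _rng_for(seed: int, *tags: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed)] + [_stable_offset(t) for t in tags])
    )


def _taxonomy(n_genera: int, seed: int) -> pd.DataFrame:
    """Shared genus catalogue: names, phyla, genome sizes.

    Deterministic given the seed and identical across matrices.  The mock
    genera are present natively (the spike recruits reads from a real
    background), assigned to their true phyla.
    """
    rng = _rng_for(seed, "taxonomy")
    names, phyla = [], []
    for g, ph, _cls, _size in _MOCK_TEMPLATE:
        names.append(g)
        phyla.append(ph)
    pool = list(_PHYLUM_WEIGHTS)
    w = np.array([_PHYLUM_WEIGHTS[p] for p in pool])
    extra = rng.choice(len(pool), size=n_genera - len(names), p=w / w.sum())
    for i, k in enumerate(extra):
        names.append(f"Genus{i + 9:04d}")
        phyla.append(pool[k])
    sizes = np.exp(rng.normal(np.log(4e6), 0.4, size=n_genera))
    for i, (g, _ph, _cls, size) in enumerate(_MOCK_TEMPLATE):
        sizes[i] = size
    meta = pd.DataFrame(
        {"phylum": phyla, "genome_size_bp": sizes}, index=pd.Index(names, name="genus")
    )
    return meta


def simulate_baseline(
    matrix_id: str, n_genera: int, seed: int
) -> tuple[pd.Series, pd.Series]:
    """Baseline (0 h) expected relative abundances for one sample matrix.

    Log-abundances combine a community core shared by all matrices, a
    sample-type component (pig feces P* vs sewage S*), and a matrix-specific
    component, so matrices are mutually distinct while the two pig samples
    resemble each other more than they resemble sewage.  Returns the closed
    profile and the per-genus phylum assignment.
    """
    if n_genera < 20:
        raise ValueError("n_genera must be >= 20")
    meta = _taxonomy(n_genera, seed)
    core = _rng_for(seed, "core").normal(0.0, 2.0, size=n_genera)
    env = "pig" if matrix_id.startswith("P") else "sewage"
    env_dev = _rng_for(seed, f"env:{env}").normal(0.0, 1.0, size=n_genera)
    mat_dev = _rng_for(seed, f"matrix:{matrix_id}").normal(0.0, 0.8, size=n_genera)
    logab = core + env_dev + mat_dev
    # eukaryotes are a minor community fraction
    logab[np.isin(meta["phylum"].to_numpy(), EUKARYOTE_PHYLA)] -= 3.0
    profile = np.exp(logab)
    profile /= profile.sum()
    return (
        pd.Series(profile, index=meta.index, name=matrix_id),
        meta["phylum"].copy(),
    )


def apply_storage_effect(
    baseline: pd.Series,
    condition: Condition,
    effect_model: EffectModel,
    phylum: pd.Series,
    taxon_deviation: pd.Series | None = None,
) -> pd.Series:
    """Expected profile under a storage condition.

    log2 abundance = log2(baseline) + phylum_effect(temp) × scaled_time
    + freeze_thaw_slope × cycles + taxon deviation, then re-closed to sum 1.
    Time is scaled linearly onto [0, 1] over the 0–64 h span.  At 0 h the
    baseline is returned exactly.
    """
    if condition.time_h == 0:
        return baseline.copy()
    ph = phylum.reindex(baseline.index)
    rates = np.array([effect_model.rate(condition.temperature_c, p) for p in ph])
    scaled = condition.time_h / effect_model.time_scale_h
    shift = rates * scaled
    if condition.freeze_thaw_cycles:
        ft = np.array(
            [effect_model.freeze_thaw_effects.get(p, 0.0) for p in ph]
        )
        shift = shift + ft * condition.freeze_thaw_cycles
    if taxon_deviation is not None:
        shift = shift + taxon_deviation.reindex(baseline.index).to_numpy()
    profile = baseline.to_numpy() * np.exp2(shift)
    profile = profile / profile.sum()
    return pd.Series(profile, index=baseline.index, name=baseline.name)


def sample_counts(
    expected_profile,
    library_size: float,
    nb_dispersion: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a gamma-Poisson (negative binomial) count vector.

    Means are profile × library size; dispersion 0 degenerates to Poisson.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    mean = np.asarray(expected_profile, dtype=float) * float(library_size)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if nb_dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / nb_dispersion
    lam = rng.gamma(shape, mean * nb_dispersion)
    return rng.poisson(lam)


def spike_mock(
    mean_counts: pd.Series,
    mock_spec: MockSpec,
    spike_fraction: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Add expected mock-community fragments on top of native means.

    Each member contributes reads proportional to cells_per_mg ×
    genome_size_bp × extraction_efficiency, scaled so the whole spike makes
    up ``spike_fraction`` of the native library.  Native counts of mock
    genera are retained beneath the spike.  Returns (spiked means, planted
    contributions per member).
    """
    frac = mock_spec.spike_fraction if spike_fraction is None else spike_fraction
    if frac < 0:
        raise ValueError("spike fraction must be >= 0")
    missing = [m.genus for m in mock_spec.members if m.genus not in mean_counts.index]
    if missing:
        raise ValueError(f"mock genera absent from the count index: {missing}")
    weights = np.array(
        [
            m.cells_per_mg * m.genome_size_bp * m.extraction_efficiency
            for m in mock_spec.members
        ]
    )
    total = frac * float(mean_counts.sum())
    contrib = pd.Series(
        weights / weights.sum() * total,
        index=pd.Index(mock_spec.genera, name="genus"),
    )
    spiked = mean_counts.copy()
    spiked.loc[contrib.index] = spiked.loc[contrib.index] + contrib
    return spiked, contrib


def simulate_amr(
    taxon_counts: pd.Series,
    host_map: pd.Series,
    gene_lengths_bp: pd.Series,
    copy_factors: pd.Series,
    nb_dispersion: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> pd.Series:
    """AMR gene counts linked to their host taxa.

    Gene mean = host taxon count × copy factor × gene length (kb), with
    gamma-Poisson noise; genes whose host is absent get zero mean, so the
    resistome co-varies with taxonomy by construction.
    """
    unknown = [g for g, t in host_map.items() if t not in taxon_counts.index]
    if unknown:
        raise ValueError(f"genes mapped to unknown taxa: {unknown}")
    host_counts = taxon_counts.reindex(host_map.to_numpy()).to_numpy(dtype=float)
    mean = (
        host_counts
        * copy_factors.reindex(host_map.index).to_numpy()
        * (gene_lengths_bp.reindex(host_map.index).to_numpy() / 1000.0)
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if nb_dispersion == 0:
        counts = rng.poisson(mean)
    else:
        lam = np.where(mean > 0, rng.gamma(1.0 / nb_dispersion, mean * nb_dispersion), 0.0)
        counts = rng.poisson(lam)
    return pd.Series(counts, index=host_map.index, name=taxon_counts.name)


@dataclass
class GroundTruth:
    """Everything planted by the generator, for scoring downstream stages."""

    expected_relative: pd.DataFrame  # taxon × sample, includes the spike
    spike_contributions: pd.DataFrame  # genus × sample, expected fragments
    expected_library: pd.Series  # per-sample expected total fragments
    amr_host: pd.Series  # gene → host genus
    amr_copy_factors: pd.Series
    effect_model: EffectModel
    design: DesignSpec


@dataclass
class SimulatedDataset:
    taxa: pd.DataFrame  # genus × sample raw fragment counts
    amr: pd.DataFrame  # gene × sample raw fragment counts
    sheet: pd.DataFrame  # sample metadata, indexed by sample_id
    taxa_meta: pd.DataFrame  # genus → phylum, genome size
    gene_meta: pd.DataFrame  # gene → class, length, host
    truth: GroundTruth

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.taxa.to_csv(out / "taxa_counts.tsv", sep="\t")
        self.amr.to_csv(out / "amr_counts.tsv", sep="\t")
        self.sheet.to_csv(out / "sample_sheet.tsv", sep="\t")
        self.taxa_meta.to_csv(out / "taxa_meta.tsv", sep="\t")
        self.gene_meta.to_csv(out / "gene_meta.tsv", sep="\t")
        self.truth.expected_relative.to_csv(out / "truth_expected_relative.tsv", sep="\t")
        self.truth.spike_contributions.to_csv(out / "truth_spike_contributions.tsv", sep="\t")


def _gene_catalogue(meta: pd.DataFrame, baseline_mean: pd.Series, n_genes: int, seed: int):
    """Assign each AMR gene a host genus (abundance-weighted among bacteria),
    a class drawn from its host phylum's preference, a length and a copy factor."""
    rng = _rng_for(seed, "amr")
    bacterial = meta.index[meta["phylum"].isin(BACTERIAL_PHYLA)]
    w = baseline_mean.reindex(bacterial).to_numpy()
    w = w / w.sum()
    hosts = rng.choice(bacterial, size=n_genes, p=w)
    classes = []
    for h in hosts:
        ph = meta.loc[h, "phylum"]
        cw = np.array(_CLASS_WEIGHTS_BY_PHYLUM[ph])
        classes.append(AMR_CLASSES[rng.choice(len(AMR_CLASSES), p=cw / cw.sum())])
    lengths = rng.integers(500, 3000, size=n_genes).astype(float)
    copies = np.exp(rng.normal(np.log(0.02), 0.5, size=n_genes))
    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    gmeta = pd.DataFrame(
        {
            "amr_class": classes,
            "length_bp": lengths,
            "host_genus": hosts,
            "copy_factor": copies,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return gmeta


def generate_dataset(
    design: DesignSpec | None = None,
    effect_model: EffectModel | None = None,
    mock_spec: MockSpec | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate the full storage experiment with ground truth.

    One sample per (matrix, condition, replicate, spiked state).  Taxon
    deviations around the phylum effect are drawn once per (matrix,
    temperature class), so replicates share their expected profile; noise is
    applied exactly once, to the combined native + spike mean.
    """
    design = design or DesignSpec()
    em = effect_model or default_effect_model()
    meta = _taxonomy(design.n_genera, seed)
    baselines = {
        m: simulate_baseline(m, design.n_genera, seed)[0] for m in design.matrices
    }
    mean_baseline = pd.concat(baselines.values(), axis=1).mean(axis=1)
    gmeta = _gene_catalogue(meta, mean_baseline, design.n_amr_genes, seed)

    taxa_cols, amr_cols, sheet_rows = {}, {}, []
    truth_rel, truth_spike, truth_lib = {}, {}, {}

    for matrix in design.matrices:
        base = baselines[matrix]
        mock = mock_spec or default_mock_spec(matrix)
        # one taxon-deviation vector per temperature class, shared by its conditions
        dev_rng = _rng_for(seed, f"dev:{matrix}")
        dev_by_class: dict[str, pd.Series] = {}
        for cls in ("frozen", "5", "22"):
            dev_by_class[cls] = pd.Series(
                dev_rng.normal(0.0, em.taxon_effect_sd, size=len(base)),
                index=base.index,
            )
        for cond in design.conditions(matrix):
            if cond.time_h == 0:
                dev = None
            else:
                cls = (
                    "frozen"
                    if cond.temperature_c in FROZEN_TEMPS
                    else str(int(cond.temperature_c))
                )
                dev = dev_by_class[cls]
            expected = apply_storage_effect(base, cond, em, meta["phylum"], dev)
            for spiked in design.spiked_states:
                for rep in range(1, design.replicates + 1):
                    sid = f"{matrix}_{cond.label}_r{rep}" + ("_sp" if spiked else "")
                    rng = _rng_for(seed, f"sample:{sid}")
                    lib = design.library_size * np.exp(
                        rng.normal(0.0, em.library_size_lognormal_sd)
                    )
                    mean = expected * lib
                    if spiked:
                        mean, contrib = spike_mock(mean, mock)
                    else:
                        contrib = pd.Series(0.0, index=pd.Index(mock.genera, name="genus"))
                    counts = sample_counts(mean / mean.sum(), mean.sum(), em.nb_dispersion, rng)
                    taxa_cols[sid] = pd.Series(counts, index=base.index)
                    amr_cols[sid] = simulate_amr(
                        taxa_cols[sid],
                        gmeta["host_genus"],
                        gmeta["length_bp"],
                        gmeta["copy_factor"],
                        em.nb_dispersion,
                        rng,
                    )
                    truth_rel[sid] = mean / mean.sum()
                    truth_spike[sid] = contrib
                    truth_lib[sid] = float(mean.sum())
                    sheet_rows.append(
                        {
                            "sample_id": sid,
                            "matrix": matrix,
                            "temperature_C": cond.temperature_c,
                            "time_h": cond.time_h,
                            "replicate": rep,
                            "spiked": spiked,
                            "freeze_thaw_cycles": cond.freeze_thaw_cycles,
                            "condition": cond.label,
                        }
                    )

    taxa = pd.DataFrame(taxa_cols)
    taxa.index.name = "genus"
    amr = pd.DataFrame(amr_cols)
    amr.index.name = "gene"
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    truth = GroundTruth(
        expected_relative=pd.DataFrame(truth_rel),
        spike_contributions=pd.DataFrame(truth_spike),
        expected_library=pd.Series(truth_lib, name="expected_library"),
        amr_host=gmeta["host_genus"].copy(),
        amr_copy_factors=gmeta["copy_factor"].copy(),
        effect_model=em,
        design=design,
    )
    return SimulatedDataset(
        taxa=taxa, amr=amr, sheet=sheet, taxa_meta=meta, gene_meta=gmeta, truth=truth
    )
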