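"""End-to-end orchestration: simulate/load → preprocess → analyze → report.

``run`` executes the full analysis as a configured, seeded, logged sequence
of stages and writes tidy TSV tables: alpha diversity, Bray-Curtis
dissimilarities and PCoA coordinates, PERMANOVA with its dispersion check,
the stored-vs-0 h dissimilarity table, constrained (CCA) inertia, pairwise
negative-binomial differential abundance with significance counts, resistome
FPKM/class summaries with taxonomy-vs-resistome Procrustes tests, and the
spike-in correction audit.  Spiked and unspiked sample sets are always
analyzed separately.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counts as _counts
from . import diversity as _div
from . import ordination as _ord
from . import resistome as _res
from . import spikefix as _spike
from . import stats as _stats
from . import synth as _synth

__all__ = ["RunConfig", "StageError", "run", "validate_inputs", "ValidationReport"]

log = logging.getLogger("storagefx")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_dir`` (TSV tables written by
    :meth:`storagefx.synth.SimulatedDataset.write`) or ``design`` (simulate
    in-process) is used; by default a synthetic dataset is generated.
    """

    outdir: str | Path = "storagefx_run"
    seed: int = 0
    input_dir: str | Path | None = None
    design: _synth.DesignSpec | None = None
    effect_model: _synth.EffectModel | None = None
    diffabund_alpha: float = 0.01
    kw_alpha: float = 0.05
    betadisper_alpha: float = 0.05
    permanova_permutations: int = 999
    protest_permutations: int = 999
    stages: tuple = (
        "alpha",
        "beta",
        "cca",
        "diffabund",
        "resistome",
        "spikefix",
    )

    def __post_init__(self):
        if self.input_dir is not None and self.design is not None:
            raise ValueError("provide input_dir or a design, not both")
        for name, a in [
            ("diffabund_alpha", self.diffabund_alpha),
            ("kw_alpha", self.kw_alpha),
            ("betadisper_alpha", self.betadisper_alpha),
        ]:
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    taxa: pd.DataFrame,
    sheet: pd.DataFrame,
    taxa_meta: pd.DataFrame | None = None,
    amr: pd.DataFrame | None = None,
    gene_meta: pd.DataFrame | None = None,
    expected_replicates: int | None = None,
) -> ValidationReport:
    """Consistency checks on an input bundle (fatal errors vs warnings)."""
    rep = ValidationReport()
    missing = [s for s in taxa.columns if s not in sheet.index]
    if missing:
        rep.errors.append(f"samples in counts missing from sample sheet: {missing}")
    extra = [s for s in sheet.index if s not in taxa.columns]
    if extra:
        rep.warnings.append(f"sheet samples absent from counts: {extra}")
    if (taxa.to_numpy() < 0).any():
        rep.errors.append("negative entries in taxa counts")
    if taxa.index.duplicated().any():
        rep.errors.append("duplicate feature ids in taxa counts")
    if taxa_meta is not None:
        unannotated = [g for g in taxa.index if g not in taxa_meta.index]
        if unannotated:
            rep.errors.append(f"genera without metadata (genome size): {unannotated}")
        elif (taxa_meta.loc[taxa.index, "genome_size_bp"] <= 0).any():
            rep.errors.append("non-positive genome sizes")
    if amr is not None:
        if (amr.to_numpy() < 0).any():
            rep.errors.append("negative entries in AMR counts")
        if gene_meta is not None:
            un = [g for g in amr.index if g not in gene_meta.index]
            if un:
                rep.errors.append(f"AMR genes without metadata: {un}")
    if expected_replicates is not None and not sheet.empty:
        cells = sheet.groupby(["matrix", "condition", "spiked"]).size()
        bad = cells[cells != expected_replicates]
        if not bad.empty:
            rep.warnings.append(
                f"design cells without {expected_replicates} replicates: "
                f"{bad.to_dict()}"
            )
    return rep


def _load_inputs(cfg: RunConfig):
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        taxa = _counts.read_table(d / "taxa_counts.tsv")
        amr = _counts.read_table(d / "amr_counts.tsv")
        sheet = pd.read_csv(d / "sample_sheet.tsv", sep="\t", index_col=0)
        taxa_meta = pd.read_csv(d / "taxa_meta.tsv", sep="\t", index_col=0)
        gene_meta = pd.read_csv(d / "gene_meta.tsv", sep="\t", index_col=0)
        return taxa, amr, sheet, taxa_meta, gene_meta, None
    ds = _synth.generate_dataset(
        design=cfg.design, effect_model=cfg.effect_model, seed=cfg.seed
    )
    return ds.taxa, ds.amr, ds.sheet, ds.taxa_meta, ds.gene_meta, ds


def _analysis_conditions(sheet: pd.DataFrame) -> pd.Series:
    return sheet["condition"]


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the report bundle and writes TSVs.

    On stage failure, outputs produced so far are moved under
    ``outdir/partial`` and a :class:`StageError` naming the stage is raised.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    bundle: dict = {}
    t_all = time.time()

    def stage(name, fn):
        if name not in ("simulate", "validate") and name not in config.stages:
            log.info("stage %s skipped (not enabled)", name)
            manifest["stages"][name] = {"status": "skipped"}
            return
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            partial = out / "partial"
            partial.mkdir(exist_ok=True)
            for f in out.glob("*.tsv"):
                f.rename(partial / f.name)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(name, exc) from exc
        dt = time.time() - t0
        # a stage may mark itself skipped (e.g. spikefix without spiked data)
        if manifest["stages"].get(name, {}).get("status") != "skipped":
            manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
        log.info("stage %s: done in %.2fs", name, dt)

    # ---- simulate / load -------------------------------------------------
    def _simulate():
        taxa, amr, sheet, taxa_meta, gene_meta, ds = _load_inputs(config)
        bundle.update(
            taxa=taxa, amr=amr, sheet=sheet, taxa_meta=taxa_meta,
            gene_meta=gene_meta, dataset=ds,
        )
        if ds is not None:
            ds.write(out / "inputs")

    stage("simulate", _simulate)

    def _validate():
        rep = validate_inputs(
            bundle["taxa"], bundle["sheet"], bundle["taxa_meta"],
            bundle["amr"], bundle["gene_meta"],
        )
        bundle["validation"] = rep
        if not rep.ok:
            raise ValueError("; ".join(rep.errors))

    stage("validate", _validate)

    sheet = bundle["sheet"]
    spike_states = sorted(sheet["spiked"].unique())

    def _subset(spiked):
        ids = sheet.index[sheet["spiked"] == spiked]
        return bundle["taxa"][ids], bundle["amr"][ids], sheet.loc[ids]

    tag = {False: "unspiked", True: "spiked"}

    # ---- alpha diversity --------------------------------------------------
    def _alpha():
        frames = []
        for sp in spike_states:
            taxa, _, sub = _subset(sp)
            a = _div.alpha_table(taxa)
            a["spiked"] = sp
            frames.append(a)
        alpha = pd.concat(frames)
        bundle["alpha"] = alpha
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")

    stage("alpha", _alpha)

    # ---- beta diversity: distances, PCoA, PERMANOVA, Table-1 analog ------
    def _beta():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        perm_rows, table1_frames = [], []
        for sp in spike_states:
            taxa, _, sub = _subset(sp)
            norm = _counts.total_sum_scale(
                _counts.genome_size_normalize(
                    taxa, bundle["taxa_meta"]["genome_size_bp"]
                )
            )
            dm = _ord.bray_curtis(_ord.hellinger(norm))
            dm.to_frame().to_csv(out / f"distances_{tag[sp]}.tsv", sep="\t")
            res = _ord.pcoa(dm)
            res.coordinates.iloc[:, :10].to_csv(
                out / f"pcoa_coordinates_{tag[sp]}.tsv", sep="\t"
            )
            bundle[f"dm_{tag[sp]}"] = dm
            bundle[f"pcoa_{tag[sp]}"] = res
            # overall matrix effect, then per-matrix storage-condition effect
            if sub["matrix"].nunique() >= 2:
                pr = _stats.permanova(
                    dm, sub["matrix"], config.permanova_permutations, rng
                )
                bd = _stats.betadisper(
                    dm, sub["matrix"], config.permanova_permutations, rng
                )
                perm_rows.append(
                    {
                        "spiked": sp, "scope": "all", "factor": "matrix",
                        "pseudo_F": pr.pseudo_f, "R2": pr.r2, "p_value": pr.p_value,
                        "betadisper_p": bd.p_value,
                    }
                )
            else:
                log.info("overall matrix PERMANOVA skipped: single matrix")
            for matrix, msheet in sub.groupby("matrix"):
                core = msheet.index[msheet["freeze_thaw_cycles"] == 0]
                sdm = dm.subset(list(core))
                cond = msheet.loc[core, "condition"]
                pr_m = _stats.permanova(
                    sdm, cond, config.permanova_permutations, rng
                )
                bd_m = _stats.betadisper(
                    sdm, cond, config.permanova_permutations, rng
                )
                perm_rows.append(
                    {
                        "spiked": sp, "scope": matrix, "factor": "condition",
                        "pseudo_F": pr_m.pseudo_f, "R2": pr_m.r2,
                        "p_value": pr_m.p_value, "betadisper_p": bd_m.p_value,
                    }
                )
                t1 = _stats.dissimilarity_to_baseline(sdm, msheet.loc[core])
                t1["spiked"] = sp
                table1_frames.append(t1)
        perm = pd.DataFrame(perm_rows)
        perm.to_csv(out / "permanova.tsv", sep="\t", index=False)
        table1 = pd.concat(table1_frames, ignore_index=True)
        table1.to_csv(out / "dissimilarity_to_baseline.tsv", sep="\t", index=False)
        bundle["permanova"] = perm
        bundle["table1"] = table1

    stage("beta", _beta)

    # ---- constrained ordination -------------------------------------------
    def _cca():
        rows = []
        for sp in spike_states:
            taxa, _, sub = _subset(sp)
            for matrix, msheet in sub.groupby("matrix"):
                core = msheet.index[msheet["freeze_thaw_cycles"] == 0]
                res = _ord.cca(taxa[core], msheet.loc[core, "condition"])
                rows.append(
                    {
                        "spiked": sp,
                        "matrix": matrix,
                        "total_inertia": res.total_inertia,
                        "constrained_inertia": res.constrained_inertia,
                        "constrained_fraction": res.constrained_inertia
                        / res.total_inertia,
                    }
                )
                bundle[f"cca_{tag[sp]}_{matrix}"] = res
        cca_tab = pd.DataFrame(rows)
        cca_tab.to_csv(out / "cca_inertia.tsv", sep="\t", index=False)
        bundle["cca"] = cca_tab

    stage("cca", _cca)

    # ---- differential abundance --------------------------------------------
    def _diffabund():
        all_rows = []
        counts_frames = []
        for sp in spike_states:
            taxa, _, sub = _subset(sp)
            for matrix, msheet in sub.groupby("matrix"):
                core = msheet.index[msheet["freeze_thaw_cycles"] == 0]
                raw = taxa[core]
                sf = _stats.custom_size_factors(raw)
                cond = msheet.loc[core, "condition"]
                results = {}
                for a, b in combinations(sorted(cond.unique()), 2):
                    ids = cond.index[cond.isin([a, b])]
                    res = _stats.nb_wald_test(
                        raw[ids], sf[ids], cond[ids], comparison=(a, b),
                        alpha=config.diffabund_alpha,
                    )
                    results[(a, b)] = res
                    t = res.table.reset_index()
                    t.insert(0, "matrix", matrix)
                    t.insert(1, "spiked", sp)
                    t.insert(2, "comparison", f"{a} vs {b}")
                    all_rows.append(t)
                sc = _stats.significance_counts(results)
                sc = sc.reset_index().assign(matrix=matrix, spiked=sp)
                counts_frames.append(sc)
        da = pd.concat(all_rows, ignore_index=True)
        da.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        sig = pd.concat(counts_frames, ignore_index=True)
        sig.to_csv(out / "significance_counts.tsv", sep="\t", index=False)
        bundle["diffabund"] = da
        bundle["significance_counts"] = sig

    stage("diffabund", _diffabund)

    # ---- resistome -----------------------------------------------------------
    def _resistome():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        rows = []
        for sp in spike_states:
            taxa, amr, sub = _subset(sp)
            btot = _res.bacterial_totals(
                taxa, bundle["taxa_meta"], _synth.BACTERIAL_PHYLA
            )
            fp = _res.fpkm(amr, bundle["gene_meta"]["length_bp"], btot)
            summ = _res.class_abundance(fp, bundle["gene_meta"]["amr_class"], sub)
            fp.to_csv(out / f"amr_fpkm_{tag[sp]}.tsv", sep="\t")
            summ["classes"].to_csv(out / f"amr_class_fpkm_{tag[sp]}.tsv", sep="\t")
            summ["total"].rename("total_fpkm").to_csv(
                out / f"amr_total_fpkm_{tag[sp]}.tsv", sep="\t"
            )
            summ["matrix_mean_shares_pct"].to_csv(
                out / f"amr_class_shares_{tag[sp]}.tsv", sep="\t"
            )
            bundle[f"fpkm_{tag[sp]}"] = fp
            bundle[f"amr_summary_{tag[sp]}"] = summ
            pro = _res.resistome_vs_taxonomy(
                taxa, amr, sub, config.protest_permutations, rng
            )
            for matrix, res in pro.items():
                rows.append(
                    {
                        "spiked": sp, "matrix": matrix, "m2": res.m2,
                        "correlation": res.correlation, "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                    }
                )
        pro_tab = pd.DataFrame(rows)
        pro_tab.to_csv(out / "procrustes_resistome.tsv", sep="\t", index=False)
        bundle["procrustes"] = pro_tab

    stage("resistome", _resistome)

    # ---- spike correction -----------------------------------------------------
    def _spikefix():
        if True not in spike_states or False not in spike_states:
            log.info("spikefix skipped: need both spiked and unspiked samples")
            manifest["stages"]["spikefix"] = {
                "status": "skipped",
                "reason": "no spiked/unspiked pair in the data",
            }
            bundle["spikefix"] = None
            return
        taxa_s, _, sheet_s = _subset(True)
        taxa_u, _, sheet_u = _subset(False)
        mock = _synth.default_mock_spec().genera
        sheet_all = pd.concat([sheet_s, sheet_u])
        corr = _spike.correct_spiked(taxa_s, taxa_u, mock, sheet_all)
        corr.corrected.to_csv(out / "spike_corrected.tsv", sep="\t")
        audit = pd.DataFrame(
            {
                "factor": corr.factors,
            }
        )
        audit.to_csv(out / "spike_factors.tsv", sep="\t")
        profiles = _spike.mock_condition_profiles(corr.corrected, sheet_all)
        profiles.to_csv(out / "mock_condition_profiles.tsv", sep="\t", index=False)
        bundle["spikefix"] = corr
        bundle["mock_profiles"] = profiles

    stage("spikefix", _spikefix)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
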