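"""Per-gene scan orchestration: summary tables in the style of a
multi-gene diversity/selection survey.

``run_scan`` walks a list of genes (FASTA alignment + BED regions + shared
population map), computes per-region diversity, coding d_N/d_S against the
designated outgroup, outgroup-polarized neutrality tests with
coalescent-null and (optionally) genome-wide empirical percentiles, and
F_ST between two demes. One null distribution is simulated per
(gene, sample subset) because n and theta differ per locus; every null seed
is derived deterministically from the run seed and logged, so any percentile
is replayable.

Statistics computed here are the same module calls a user would make
directly; the pipeline adds only bookkeeping.
"""

from __future__ import annotations

import logging
import math
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignments import (
    PopulationMap,
    RegionAnnotation,
    SequenceAlignment,
    complete_deletion_mask,
    polarize,
    read_bed,
    read_fasta,
    read_population_map,
)
from .coalescent import (
    DemographicModel,
    SimConfig,
    percentile_of,
    simulate_null,
)
from .differentiation import hudson_fst
from .divergence import nei_gojobori_dn_ds
from .diversity import diversity_summary
from .neutrality import neutrality_result, pairwise_diff_mean

logger = logging.getLogger("zeascan.scan")


@dataclass
class GeneEntry:
    name: str
    fasta: Path
    bed: Path
    outgroup: str
    theta: float | None = None
    frame_offset: int = 0


@dataclass
class ScanConfig:
    genes: list[GeneEntry]
    popmap_path: Path
    outdir: Path
    reps: int = 10000
    seed: int = 0
    demography: DemographicModel = field(
        default_factory=DemographicModel.constant
    )
    main_populations: list[str] | None = None  # None = all non-outgroup
    fst_populations: tuple[str, str] | None = None
    empirical_dist: Path | None = None
    empirical_populations: list[str] | None = None
    keep_going: bool = False
    dn_ds_mode: str = "average"

    def __post_init__(self) -> None:
        if self.reps < 1000:
            logger.warning(
                "reps = %d < 1000: percentile calls will be coarse", self.reps
            )


def load_scan_config(path) -> ScanConfig:
    """Parse the flat TOML scan configuration."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = path.parent

    def respath(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    demo_raw = raw.get("demography", {})
    if "bottleneck" in demo_raw:
        td, tb, xb, xa = demo_raw["bottleneck"]
        demography = DemographicModel.bottleneck(td, tb, xb, xa)
    elif "epochs" in demo_raw:
        demography = DemographicModel(
            epochs=tuple(tuple(e) for e in demo_raw["epochs"])
        )
    else:
        demography = DemographicModel.constant()
    genes = [
        GeneEntry(
            name=g["name"],
            fasta=respath(g["fasta"]),
            bed=respath(g["bed"]),
            outgroup=g["outgroup"],
            theta=g.get("theta"),
            frame_offset=int(g.get("frame_offset", 0)),
        )
        for g in raw["genes"]
    ]
    fst_pops = raw.get("fst_populations")
    return ScanConfig(
        genes=genes,
        popmap_path=respath(raw["popmap"]),
        outdir=respath(raw.get("outdir", "scan_out")),
        reps=int(raw.get("reps", 10000)),
        seed=int(raw.get("seed", 0)),
        demography=demography,
        main_populations=raw.get("populations"),
        fst_populations=tuple(fst_pops) if fst_pops else None,
        empirical_dist=(
            respath(raw["empirical_dist"]) if "empirical_dist" in raw else None
        ),
        empirical_populations=raw.get("empirical_populations"),
        keep_going=bool(raw.get("keep_going", False)),
        dn_ds_mode=raw.get("dn_ds_mode", "average"),
    )


def read_empirical_distribution(path) -> np.ndarray:
    """One statistic value per line (blank lines and '#' comments skipped)."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                values.append(float(line))
    if not values:
        raise ValueError(f"{path}: no values")
    return np.sort(np.asarray(values))


def derive_null_seed(run_seed: int, gene: str, subset: str) -> int:
    """Stable per-(gene, subset) seed below 2**31, derived from the run seed."""
    key = [run_seed] + [ord(ch) for ch in f"{gene}:{subset}"]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _significance(percentile: float) -> str:
    if math.isnan(percentile):
        return "NA"
    if percentile <= 2.5 or percentile >= 97.5:
        return "significant"
    if percentile <= 5.0 or percentile >= 95.0:
        return "marginal"
    return ""


def _estimate_theta(aln: SequenceAlignment, popmap: PopulationMap,
                    subset_ids: list[str]) -> float:
    """Per-locus theta for the null: Watterson from the sister population
    (the wild-progenitor analog) when available, else from the subset."""
    from .diversity import watterson_theta

    sister = [s for s in popmap.samples_in("sister") if s in aln.sample_ids]
    source = sister if len(sister) >= 2 else subset_ids
    cols = complete_deletion_mask(aln, source)
    theta_site = watterson_theta(aln, source, cols)
    subset_cols = complete_deletion_mask(aln, subset_ids)
    return theta_site * len(subset_cols)


def _neutrality_row(aln, popmap, entry, subset_ids, subset_name, config,
                    empirical, log_lines):
    """Neutrality statistics + percentiles for one (gene, subset)."""
    row = {
        "gene": entry.name, "subset": subset_name, "n": len(subset_ids),
        "S": np.nan, "eta": np.nan, "eta_e": np.nan, "pi_hat": np.nan,
        "tajima_d": np.nan, "fu_li_d": np.nan, "fu_li_f": np.nan,
        "pct_sim_tajima_d": np.nan, "pct_sim_fu_li_d": np.nan,
        "pct_sim_fu_li_f": np.nan, "pct_empirical_tajima_d": np.nan,
        "significance": "NA", "unpolarizable": 0, "null_seed": np.nan,
        "null_theta": np.nan,
    }
    sub_popmap = PopulationMap(
        {s: popmap.assignments[s] for s in subset_ids + [entry.outgroup]},
        frozenset({entry.outgroup}),
    )
    cols = complete_deletion_mask(aln, subset_ids + [entry.outgroup])
    matrix, diag = polarize(aln, sub_popmap, entry.outgroup, cols)
    row["unpolarizable"] = diag.unpolarizable
    pi_hat = pairwise_diff_mean(aln, subset_ids)
    res = neutrality_result(matrix)
    row.update(
        S=res.s, eta=res.eta, eta_e=res.eta_e, pi_hat=pi_hat,
        tajima_d=res.tajima_d, fu_li_d=res.fu_li_d, fu_li_f=res.fu_li_f,
    )
    if res.s == 0 or math.isnan(res.tajima_d):
        return row  # monomorphic locus: flagged-NA row, no percentiles
    if config.reps >= 1:
        theta = entry.theta
        if theta is None:
            theta = _estimate_theta(aln, popmap, subset_ids)
        null_seed = derive_null_seed(config.seed, entry.name, subset_name)
        row["null_seed"] = null_seed
        row["null_theta"] = theta
        sim = SimConfig(n=len(subset_ids), theta=theta, reps=config.reps,
                        seed=null_seed)
        nulls = simulate_null(sim, config.demography,
                              ["tajima_d", "fu_li_d", "fu_li_f"])
        for stat, col in (("tajima_d", "pct_sim_tajima_d"),
                          ("fu_li_d", "pct_sim_fu_li_d"),
                          ("fu_li_f", "pct_sim_fu_li_f")):
            row[col] = percentile_of(row[stat], nulls[stat].values)
        row["significance"] = _significance(row["pct_sim_tajima_d"])
        log_lines.append(
            f"null gene={entry.name} subset={subset_name} "
            f"n={len(subset_ids)} theta={theta:.4f} reps={config.reps} "
            f"seed={null_seed}"
        )
    if empirical is not None:
        emp_ids = subset_ids
        if config.empirical_populations:
            emp_ids = [
                s for s in subset_ids
                if popmap.assignments[s] in config.empirical_populations
            ]
        if len(emp_ids) >= 4:
            from .neutrality import tajimas_d

            d_emp = tajimas_d(aln, emp_ids)
            if not math.isnan(d_emp):
                row["pct_empirical_tajima_d"] = percentile_of(d_emp, empirical)
    return row


def run_scan(config: ScanConfig) -> dict[str, pd.DataFrame]:
    """Run the full per-gene scan and write the summary tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    popmap = read_population_map(config.popmap_path)
    main_pops = config.main_populations or popmap.populations()
    fst_pops = config.fst_populations
    if fst_pops is None and len(main_pops) >= 2:
        fst_pops = (main_pops[0], main_pops[1])
    empirical = (
        read_empirical_distribution(config.empirical_dist)
        if config.empirical_dist else None
    )

    log_lines = [
        f"zeascan {__version__} | python {sys.version.split()[0]}",
        f"seed={config.seed} reps={config.reps} "
        f"demography={config.demography.epochs}",
        f"main_populations={main_pops} fst={fst_pops}",
    ]
    table1_rows, table2_rows, fst_rows, subpop_rows = [], [], [], []
    errors: list[str] = []
    for entry in config.genes:
        try:
            aln = read_fasta(entry.fasta)
            regions = read_bed(entry.bed, coding_frame_offset=entry.frame_offset)
            if entry.outgroup not in aln.sample_ids:
                raise ValueError(
                    f"{entry.name}: outgroup {entry.outgroup!r} not in alignment"
                )
            main_ids = [
                s for s in popmap.ingroup_ids()
                if popmap.assignments[s] in main_pops and s in aln.sample_ids
            ]
            # --- table 1 analog: per-region diversity + coding divergence
            classes = {k for _, _, k in regions.intervals}
            for klass in ("coding", "intron", "five_prime"):
                if klass not in classes:
                    continue
                summ = diversity_summary(aln, regions, main_ids, klass)
                t1 = {"gene": entry.name, "region": klass, "n": summ.n,
                      "L_eff": summ.l_eff, "S": summ.s, "pi": summ.pi,
                      "pi_se": summ.pi_se, "theta_w": summ.theta_w,
                      "pi_a": summ.pi_a, "pi_s": summ.pi_s,
                      "pi_a_over_pi_s": summ.pi_a_over_pi_s,
                      "aa_poly_per_100": summ.aa_poly_per_100,
                      "d_n": np.nan, "d_s": np.nan, "dn_ds": np.nan}
                if klass == "coding":
                    cols = regions.coding_columns_in_frame()
                    coding = {
                        s: "".join(aln.row(s)[c] for c in cols)
                        for s in main_ids + [entry.outgroup]
                    }
                    div = nei_gojobori_dn_ds(
                        [coding[s] for s in main_ids], coding[entry.outgroup],
                        outgroup_id=entry.outgroup, mode=config.dn_ds_mode,
                    )
                    t1.update(d_n=div.d_n, d_s=div.d_s, dn_ds=div.ratio)
                table1_rows.append(t1)
            # --- table 2 analog: neutrality + percentiles (main subset)
            table2_rows.append(
                _neutrality_row(aln, popmap, entry, main_ids, "main",
                                config, empirical, log_lines)
            )
            # --- per-subpopulation rows (table 5 analog)
            for pop in main_pops:
                ids = [s for s in popmap.samples_in(pop) if s in aln.sample_ids]
                if len(ids) >= 4:
                    subpop_rows.append(
                        _neutrality_row(aln, popmap, entry, ids, pop,
                                        config, empirical, log_lines)
                    )
            # --- F_ST between the two demes
            if fst_pops:
                try:
                    d = hudson_fst(aln, popmap, fst_pops[0], fst_pops[1])
                    fst_rows.append(
                        {"gene": entry.name, "pop_a": fst_pops[0],
                         "pop_b": fst_pops[1], "fst": d.fst, "h_w": d.h_w,
                         "h_b": d.h_b, "n1": d.n1, "n2": d.n2}
                    )
                except ValueError as exc:
                    log_lines.append(f"fst skipped for {entry.name}: {exc}")
        except Exception as exc:  # per-gene isolation
            msg = f"gene {entry.name} failed: {exc}"
            errors.append(msg)
            log_lines.append("ERROR " + msg)
            if not config.keep_going:
                raise

    tables = {
        "table1": pd.DataFrame(table1_rows),
        "table2": pd.DataFrame(table2_rows),
        "fst": pd.DataFrame(fst_rows),
        "per_subpop": pd.DataFrame(subpop_rows),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  na_rep="NA", float_format="%.6g")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    tables["errors"] = errors
    return tables
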