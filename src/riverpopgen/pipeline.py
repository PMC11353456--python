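"""End-to-end pipeline: simulate or load data, run the per-marker,
spatial and demographic analyses, and write one TSV table per analysis.

Every stage draws its seed deterministically from the master seed and the
stage name, so stages are reproducible independently of which other
stages are enabled.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .datatypes import GenotypeMatrix, HaplotypeAlignment, PopulationAssignment
from .msat_demography import (
    gw_m_ratio,
    gw_null_distribution,
    kimmel_beta,
    reich_g_test,
    reich_k_test,
    zhivotovsky_sk,
)
from .msat_structure import fstats, hwe_tests, msat_diversity, nei_distance
from .network import haplotype_counts, median_joining_network, rho_dating
from .seq_diversity import diversity_stats, mismatch_distribution, neutrality_tests
from .seq_structure import (
    amova,
    hudson_heterogeneity,
    kimura2p_matrix,
    pairwise_exact_tests,
)
from .simulate import SimulationConfig, simulate_microsatellites, simulate_sequences
from .spatial import ay_correlogram, geo_distance_matrix, mantel_test
from .seq_structure import pairwise_differences

logger = logging.getLogger("riverpopgen")


@dataclass
class PipelineConfig:
    out_dir: str = "riverpopgen_out"
    master_seed: int = 0
    # inputs: either file paths or a simulation config
    fasta: str | None = None
    popmap: str | None = None
    genepop: str | None = None
    simulation: SimulationConfig | None = None
    # stage toggles
    run_seq: bool = True
    run_msat: bool = True
    run_spatial: bool = True
    run_demography: bool = True
    run_network: bool = True
    # effort knobs
    perms: int = 1000
    coalescent_reps: int = 1000
    gw_reps: int = 2000
    alpha: float = 0.05
    n_distance_classes: int = 5
    amova_groups: dict[str, str] | None = None

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        """Hash of the semantically meaningful fields (where outputs go is
        not part of what was computed)."""
        payload = {
            k: v for k, v in asdict(self).items() if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[HaplotypeAlignment | None, PopulationAssignment | None, GenotypeMatrix | None]:
    aln = popmap = gm = None
    if cfg.simulation is not None:
        sim = cfg.simulation
        aln, popmap = simulate_sequences(sim)
        gm = simulate_microsatellites(sim)
    if cfg.fasta is not None:
        aln, popmap = rio.read_fasta_with_popmap(cfg.fasta, cfg.popmap)
    if cfg.genepop is not None:
        gm = rio.read_genepop(cfg.genepop)
    return aln, popmap, gm


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the enabled stages in dependency order and write TSV reports.

    Returns the table bundle that was written.  Each table carries the
    config hash and master seed in its provenance columns; a failing stage
    aborts with a stage-attributed error, leaving earlier tables on disk.
    """
    t_start = time.time()
    tables: dict[str, pd.DataFrame] = {}
    aln, popmap, gm = _load_inputs(cfg)
    stamp = {"config_hash": cfg.config_hash(), "master_seed": cfg.master_seed}

    def finish(name: str, df: pd.DataFrame) -> None:
        for k, v in stamp.items():
            df[k] = v
        tables[name] = df
        logger.info("stage %s: %d rows (%.1fs)", name, len(df), time.time() - t_start)

    if cfg.run_seq and aln is not None:
        seed = cfg.stage_seed("seq")
        div = diversity_stats(aln)
        finish(
            "seq_diversity",
            pd.DataFrame(
                [
                    {
                        "n": div.n, "sites": div.n_sites, "H": div.H,
                        "Hd": div.H_d, "Hd_sd": div.H_d_sd, "pi": div.pi,
                        "pi_sd": div.pi_sd, "k_bar": div.k_bar, "S": div.S,
                        "theta_seq": div.theta_seq,
                    }
                ]
            ),
        )
        neut = neutrality_tests(aln, cfg.coalescent_reps, seed)
        finish(
            "seq_neutrality",
            pd.DataFrame(
                [
                    {"statistic": k, "value": v, "p": neut.p_values.get(k, np.nan)}
                    for k, v in neut.statistics.items()
                ]
            ),
        )
        mm = mismatch_distribution(aln, bootstrap_reps=min(cfg.perms, 200), seed=seed)
        finish(
            "seq_mismatch",
            pd.DataFrame(
                [
                    {
                        "tau": mm.tau, "theta0": mm.theta0, "theta1": mm.theta1,
                        "ssd": mm.ssd, "raggedness": mm.rg,
                        "p_ssd": mm.p_ssd, "p_rg": mm.p_rg,
                    }
                ]
            ),
        )
        if popmap is not None and len(set(popmap.sample_to_pop.values())) > 1:
            het = hudson_heterogeneity(aln, popmap, cfg.perms, seed)
            rows = [
                {
                    "statistic": k, "value": v,
                    "p": het.p_values.get(k, np.nan),
                    "nm": het.nm.get(k, np.nan),
                }
                for k, v in het.statistics.items()
            ]
            rows.append(
                {"statistic": "chi2", "value": het.chi2, "p": het.chi2_p,
                 "nm": np.nan}
            )
            finish("seq_heterogeneity", pd.DataFrame(rows))
            pw = pairwise_exact_tests(
                aln, popmap, mcmc=(1000, 10, 500), seed=seed
            )
            recs = []
            for i, a in enumerate(pw.populations):
                for j in range(i + 1, len(pw.populations)):
                    recs.append(
                        {
                            "pop_a": a, "pop_b": pw.populations[j],
                            "exact_p": pw.exact_p[i, j],
                            "nm": pw.nm[i, j],
                            "k2p_between": pw.d_between[i, j],
                            "k2p_net": pw.d_net[i, j],
                        }
                    )
            finish("seq_pairwise", pd.DataFrame(recs))
            if cfg.amova_groups is not None:
                am = amova(aln, popmap, cfg.amova_groups, cfg.perms, seed)
                finish(
                    "seq_amova",
                    pd.DataFrame(
                        [
                            {
                                "component": k,
                                "variance": am.variance_components[k],
                                "percent": am.percentages[k],
                            }
                            for k in am.variance_components
                        ]
                    ),
                )

    msat_popmap = None
    if gm is not None and gm.populations is not None:
        coords = popmap.coordinates if popmap is not None else {}
        msat_popmap = gm.popmap(coords)

    if cfg.run_msat and gm is not None and msat_popmap is not None:
        seed = cfg.stage_seed("msat")
        div = msat_diversity(gm, msat_popmap)
        finish(
            "msat_diversity",
            pd.DataFrame(
                [
                    {
                        "locus": l,
                        "alleles": div.alleles_per_locus.get(l, 0),
                        "Ho": div.ho_per_locus.get(l, np.nan),
                        "He": div.he_per_locus.get(l, np.nan),
                    }
                    for l in div.loci
                ]
            ),
        )
        hwe = hwe_tests(gm, msat_popmap, mcmc=(1000, 10, 500), seed=seed)
        finish(
            "msat_hwe",
            pd.DataFrame(
                [
                    {
                        "locus": l, "rh_f": hwe.rh_f[l], "fis": hwe.fis[l],
                        "fisher_chi2": hwe.fisher_per_locus[l][0],
                        "fisher_df": hwe.fisher_per_locus[l][1],
                        "fisher_p": hwe.fisher_per_locus[l][2],
                    }
                    for l in hwe.loci
                ]
            ),
        )
        fs = fstats(gm, msat_popmap, randomizations=cfg.perms, seed=seed)
        finish(
            "msat_fstats",
            pd.DataFrame(
                [
                    {
                        "locus": l,
                        "F_IS": fs.per_locus[l][0],
                        "F_ST": fs.per_locus[l][1],
                        "F_IT": fs.per_locus[l][2],
                    }
                    for l in fs.loci
                ]
                + [
                    {
                        "locus": "multilocus",
                        "F_IS": fs.multilocus[0],
                        "F_ST": fs.multilocus[1],
                        "F_IT": fs.multilocus[2],
                    }
                ]
            ),
        )
        pops, D = nei_distance(gm, msat_popmap)
        finish(
            "msat_nei_distance",
            pd.DataFrame(D, index=pops, columns=pops).reset_index(
                names="population"
            ),
        )

    if cfg.run_demography and gm is not None:
        seed = cfg.stage_seed("demography")
        kb = kimmel_beta(gm)
        zk = zhivotovsky_sk(gm)
        mr = gw_m_ratio(gm)
        rk = reich_k_test(gm)
        rg = reich_g_test(gm, seed=seed, reps=min(cfg.gw_reps, 500))
        n_genes = int(2 * np.median(np.sum(gm.genotyped_mask(), axis=0)))
        theta_hat = 2.0 * zk.v_bar if np.isfinite(zk.v_bar) else 1.0
        null = gw_null_distribution(
            theta=max(theta_hat, 0.05),
            p_s=0.88,
            delta_g=3.5,
            n_genes=max(n_genes, 4),
            reps=cfg.gw_reps,
            seed=seed,
            n_loci=gm.n_loci,
            observed_m=mr.mean_m,
        )
        finish(
            "msat_demography",
            pd.DataFrame(
                [
                    {"test": "imbalance_beta", "value": kb.beta, "t": kb.t,
                     "p": kb.p},
                    {"test": "ln_beta", "value": kb.ln_beta, "t": kb.t,
                     "p": kb.p},
                    {"test": "S_k", "value": zk.s_k, "t": zk.t, "p": zk.p},
                    {"test": "mean_M", "value": mr.mean_m, "t": np.nan,
                     "p": null.rank_p},
                    {"test": "M_c", "value": null.m_c, "t": np.nan,
                     "p": np.nan},
                    {"test": "reich_k", "value": rk.n_positive, "t": np.nan,
                     "p": rk.binomial_p},
                    {"test": "reich_g", "value": rg.g, "t": np.nan,
                     "p": rg.p},
                ]
            ),
        )

    if (
        cfg.run_spatial
        and aln is not None
        and popmap is not None
        and len(popmap.coordinates) >= 3
    ):
        seed = cfg.stage_seed("spatial")
        pops, geo = geo_distance_matrix(popmap)
        d = pairwise_differences(aln)
        labels = popmap.labels_for(aln.sample_ids)
        P = len(pops)
        gen_pop = np.zeros((P, P))
        idx = {p: [i for i, l in enumerate(labels) if l == p] for p in pops}
        for i in range(P):
            for j in range(i + 1, P):
                gen_pop[i, j] = gen_pop[j, i] = d[
                    np.ix_(idx[pops[i]], idx[pops[j]])
                ].mean()
        r, p = mantel_test(gen_pop, geo, perms=cfg.perms, seed=seed)
        finish(
            "spatial_mantel",
            pd.DataFrame([{"r": r, "r_squared": r**2, "p": p}]),
        )
        coords_ind = np.array(
            [popmap.coordinates[l] for l in labels], dtype=float
        )
        dmax = d.max()
        if dmax > 0:
            ay = ay_correlogram(
                d / dmax, coords_ind, cfg.n_distance_classes,
                perms=cfg.perms, seed=seed,
            )
            finish(
                "spatial_ay",
                pd.DataFrame(
                    [
                        {
                            "class": c,
                            "lo_km": ay.scheme.boundaries[c],
                            "hi_km": ay.scheme.boundaries[c + 1],
                            "Ay": ay.ay[c],
                            "p": ay.ay_p[c],
                            "n_pairs": ay.n_pairs[c],
                        }
                        for c in ay.classes
                    ]
                ),
            )

    if cfg.run_network and aln is not None:
        seqs, counts = haplotype_counts(aln)
        if len(seqs) >= 2:
            net = median_joining_network(seqs, counts)
            # root at the most frequent haplotype unless the caller redates
            root = int(np.argmax(net.counts))
            rd = rho_dating(net, root)
            finish(
                "network_rho",
                pd.DataFrame(
                    [
                        {
                            "n_nodes": net.n_nodes,
                            "n_medians": int(np.sum(net.is_median)),
                            "total_cost": net.total_cost(),
                            "rho": rd.rho,
                            "sigma_rho": rd.sigma_rho,
                            "t_years": rd.t_years,
                            "t_sd_years": rd.t_sd_years,
                        }
                    ]
                ),
            )

    rio.write_report(tables, cfg.out_dir)
    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    return tables
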