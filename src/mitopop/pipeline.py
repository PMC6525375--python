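"""Pipeline orchestration: run every analysis stage from one config.

The config (YAML or dict) names the inputs and the stochastic settings::

    inputs:
      fasta: alignment.fasta          # or: simulate: vicariance_admixture
      population_map: popmap.csv
    seed: 1
    permutations: 1000
    replicates: 30
    rarefaction_n: null               # default: smallest region
    alpha: 0.05
    bootstrap: 100                    # mismatch-model parametric bootstrap
    neutrality_simulations: 1000

Outputs are TSV tables (diversity, rarefaction comparison, pairwise
structure, AMOVA designs, expansion fits) plus one ``results.json`` with the
scalar results.  A single seed feeds named substreams per stage, so results
are reproducible and independent of stage order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import biogeography, demography, differentiation, diversity, network, rarefaction
from .data import (
    Alignment,
    PopulationHierarchy,
    collapse_haplotypes,
    read_fasta,
    read_population_map,
    write_haplotype_table,
)
from .demography import SequenceGroup
from .simulate import make_scenario, simulate_coalescent


def load_config(path_or_dict: str | Path | Mapping) -> dict:
    if isinstance(path_or_dict, Mapping):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _load_inputs(cfg: dict) -> tuple[Alignment, PopulationHierarchy]:
    inputs = cfg.get("inputs", {})
    if "simulate" in inputs:
        scenario = make_scenario(inputs["simulate"], seed=cfg.get("seed", 1))
        aln, hier, _ = simulate_coalescent(scenario)
        return aln, hier
    for key in ("fasta", "population_map"):
        if key not in inputs:
            raise FileNotFoundError(f"config inputs missing {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    aln = read_fasta(inputs["fasta"])
    hier = read_population_map(inputs["population_map"])
    hier.validate_against(aln)
    return aln, hier


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path) -> dict[str, Any]:
    """Run the full analysis and write its report bundle to ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 1))
    permutations = int(cfg.get("permutations", 1000))
    replicates = int(cfg.get("replicates", 30))
    alpha = float(cfg.get("alpha", 0.05))
    bootstrap = int(cfg.get("bootstrap", 100))
    nsims = int(cfg.get("neutrality_simulations", 1000))
    log: list[str] = []

    aln, hier = _load_inputs(cfg)
    table = collapse_haplotypes(aln, hier)
    sites = aln.included_sites()
    L = int(sites.size)
    log.append(f"alignment: {aln.n} samples x {aln.length} bp; {L} analyzable sites (1-based)")
    log.append(f"haplotypes: {len(table.hap_ids)}")
    write_haplotype_table(table, out / "haplotype_table.csv")

    results: dict[str, Any] = {"seed": seed, "n": aln.n, "n_haplotypes": len(table.hap_ids)}

    # --- diversity -------------------------------------------------------
    summ = diversity.site_summary(aln)
    results["site_summary"] = {
        "variable": summ.n_variable,
        "parsimony_informative": summ.n_parsimony_informative,
        "singleton": summ.n_singleton,
        "base_composition": summ.base_composition,
    }
    rows = diversity.diversity_report(table, hier, sites, L)
    div_df = pd.DataFrame([r.__dict__ for r in rows])
    div_df.to_csv(out / "diversity.tsv", sep="\t", index=False)
    total = rows[-1]
    results["diversity_total"] = {
        "h": total.h, "h_sd": total.h_sd, "pi": total.pi, "pi_sd": total.pi_sd,
        "K": total.K, "Nh": total.Nh, "Nps": total.Nps,
    }

    # --- rarefaction -----------------------------------------------------
    rare = rarefaction.rarefy_regions(
        table, hier, target_n=cfg.get("rarefaction_n"), replicates=replicates,
        seed=seed, sites=sites, seq_length=L,
    )
    rare.means.to_csv(out / "rarefaction_means.tsv", sep="\t")
    comp = rarefaction.compare_regions(rare)
    comp.to_csv(out / "rarefaction_tests.tsv", sep="\t", index=False)
    results["rarefaction"] = {
        "target_n": rare.target_n,
        "means": {r: rare.means.loc[r].to_dict() for r in rare.regions},
    }

    # --- differentiation -------------------------------------------------
    dist = differentiation.tajima_nei_matrix(table, sites)
    one_f = differentiation.amova(
        table, hier, "one_level", metric="frequency",
        permutations=permutations, seed=seed,
    )
    one_d = differentiation.amova(
        table, hier, "one_level", metric="distance", dist=dist,
        permutations=permutations, seed=seed,
    )
    results["amova_one_level"] = {
        "FST": one_f.phi_st, "P_FST": one_f.p_st,
        "PhiST": one_d.phi_st, "P_PhiST": one_d.p_st,
    }
    regions = hier.regions
    amova_rows = []
    if len(regions) >= 2:
        two_f = differentiation.amova(
            table, hier, "two_level", metric="frequency",
            permutations=permutations, seed=seed,
        )
        two_d = differentiation.amova(
            table, hier, "two_level", metric="distance", dist=dist,
            permutations=permutations, seed=seed,
        )
        for res, label in ((two_d, "distance"), (two_f, "frequency")):
            amova_rows.append({
                "metric": label, "Phi_SC": res.phi_sc, "Phi_ST": res.phi_st,
                "Phi_CT": res.phi_ct, "P_SC": res.p_sc, "P_ST": res.p_st,
                "P_CT": res.p_ct,
            })
        results["amova_two_level"] = amova_rows
    pd.DataFrame(amova_rows).to_csv(out / "amova.tsv", sep="\t", index=False)

    pw = differentiation.pairwise_structure(
        table, hier, dist, permutations=permutations, seed=seed, alpha=alpha
    )
    pd.DataFrame(pw.phi_st, index=pw.populations, columns=pw.populations).to_csv(
        out / "pairwise_phist.tsv", sep="\t"
    )
    pd.DataFrame(pw.f_st, index=pw.populations, columns=pw.populations).to_csv(
        out / "pairwise_fst.tsv", sep="\t"
    )
    results["pairwise"] = {
        "critical_value": pw.critical_value,
        "n_significant_phi": int(np.triu(pw.sig_phi, 1).sum()),
        "n_significant_f": int(np.triu(pw.sig_f, 1).sum()),
    }

    gn = differentiation.gst_nst(table, dist, permutations=min(permutations, 1000), seed=seed)
    results["gst_nst"] = {"GST": gn.gst, "NST": gn.nst, "P": gn.P_nst_gt_gst}

    # --- network ---------------------------------------------------------
    net = network.build_network(table, sites=sites)
    (out / "network.dot").write_text(net.to_dot() + "\n")
    weights = network.root_weights(net)
    ancestral = next(iter(weights))
    results["network"] = {
        "limit": net.limit,
        "n_components": len(net.components()),
        "n_inferred": len(net.inferred_nodes),
        "ancestral_haplotype": ancestral,
        "root_weight": weights[ancestral],
    }

    # --- demography ------------------------------------------------------
    demo_rows = []
    group_defs = [("Total", None)] + [
        (r, hier.populations_in_region(r)) for r in regions
    ]
    for name, pops in group_defs:
        grp = SequenceGroup.from_table(table, pops, sites)
        neut = demography.neutrality_tests(grp, n_simulations=nsims, seed=seed)
        row: dict[str, Any] = {
            "group": name, "n": grp.n, "S": grp.S, "K": grp.K,
            "D": neut.D, "P_D": neut.P_D, "Fs": neut.Fs, "P_Fs": neut.P_Fs,
            "R2": neut.R2, "P_R2": neut.P_R2,
        }
        for model in ("demographic", "spatial"):
            if grp.S >= 1:
                fit = demography.fit_expansion(grp, model, bootstrap=bootstrap, seed=seed)
                row[f"{model}_tau"] = fit.tau
                row[f"{model}_SSD"] = fit.SSD
                row[f"{model}_P_SSD"] = fit.P_SSD
                row[f"{model}_rg"] = fit.rg
                row[f"{model}_P_rg"] = fit.P_rg
        demo_rows.append(row)
    pd.DataFrame(demo_rows).to_csv(out / "demography.tsv", sep="\t", index=False)
    results["demography"] = demo_rows

    # --- biogeography (only when trees + tip areas are supplied) ---------
    inputs = cfg.get("inputs", {})
    if "trees" in inputs and "tip_areas" in inputs:
        areas_df = pd.read_csv(inputs["tip_areas"], dtype=str)
        tip_areas = dict(zip(areas_df.iloc[:, 0], areas_df.iloc[:, 1]))
        trees = [
            biogeography.parse_newick(line, tip_areas, resolve_polytomies=True)
            for line in Path(inputs["trees"]).read_text().splitlines()
            if line.strip()
        ]
        diva = biogeography.s_diva_summary(trees)
        root = diva.root_clade
        results["diva"] = {
            "total_cost": diva.total_cost,
            "n_optimal": diva.n_optimal,
            "root_ranges": diva.range_frequencies(root),
            "root_events": diva.node_events[root],
        }

    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return results
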