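"""End-to-end orchestration: config-driven RCA / REL / BGM runs with joined
per-residue reports in reference coordinates."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bgm as bgm_mod
from . import rca as rca_mod
from . import rel as rel_mod
from . import seqio
from .phylo import (bionj, distance_matrix, jtt_model, gtr_model,
                    optimize_branch_lengths, read_newick, write_newick)

log = logging.getLogger("evosite")

DEFAULT_CONFIG = {
    "protein_alignment": None,
    "codon_alignment": None,
    "tree": "build",
    "reference_id": None,
    "trim_aa": 36,
    "trim_nt": 117,
    "seed": 1,
    "output_dir": "evosite_out",
    "rca": {"window": 7, "threshold": 0.5, "K": 16},
    "rel": {"constraints": "chiJ", "strong": 50.0, "weak": 10.0,
            "starts": 5, "maxfev": 400, "frequencies": "F3x4"},
    "bgm": {"min_count": 3, "pp": 0.5, "chain_length": 100_000,
            "burn_in": 10_000, "max_parents": 2},
}


@dataclass
class RunConfig:
    settings: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
        return cls(merged)

    def __getitem__(self, key):
        return self.settings[key]

    def validate(self, stages) -> None:
        s = self.settings
        if {"rca"} & set(stages) and not s["protein_alignment"] and not s["codon_alignment"]:
            raise ValueError("rca requires a protein or codon alignment")
        for stage in ("rel", "bgm"):
            if stage in stages and not s["codon_alignment"]:
                raise ValueError(f"{stage} requires a codon alignment")
        for key in ("protein_alignment", "codon_alignment"):
            if s[key] and not Path(s[key]).exists():
                raise FileNotFoundError(f"{key}: {s[key]}")
        if s["tree"] not in (None, "build") and not Path(s["tree"]).exists():
            raise FileNotFoundError(f"tree: {s['tree']}")


@dataclass
class StageArtifacts:
    profile: object = None
    rel_fit: object = None
    network: object = None
    report: pd.DataFrame = None
    summary: dict = field(default_factory=dict)


def build_tree(aln, model):
    """BIONJ on ML distances, then ML branch lengths on the fixed topology."""
    D, labels = distance_matrix(aln, model)
    tree = bionj(D, labels)
    return optimize_branch_lengths(tree, aln, model)


def _load_inputs(config: RunConfig):
    s = config.settings
    protein = codon = None
    if s["codon_alignment"]:
        nuc = seqio.read_alignment(s["codon_alignment"], seqio.NUCLEOTIDE)
        codon = seqio.as_codon_alignment(nuc)
        if s["trim_nt"]:
            codon = seqio.trim_leading(codon, int(s["trim_nt"]))
    if s["protein_alignment"]:
        protein = seqio.read_alignment(s["protein_alignment"], seqio.PROTEIN)
        if s["trim_aa"]:
            protein = seqio.trim_leading(protein, int(s["trim_aa"]))
    elif codon is not None:
        protein = codon.translate()
    return protein, codon


def _get_tree(config: RunConfig, aln, model):
    if config["tree"] not in (None, "build"):
        tree = read_newick(config["tree"])
        seqio.check_leaf_alignment_match(tree, aln)
        return tree
    log.info("building BIONJ tree with ML branch lengths")
    return build_tree(aln, model)


def run_all(config: RunConfig, stages=("rca", "rel", "bgm")) -> StageArtifacts:
    """Run the requested stages and write per-stage TSV/JSON artifacts plus a
    joined per-residue site report."""
    config.validate(stages)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    protein, codon = _load_inputs(config)
    art = StageArtifacts()

    ref_id = config["reference_id"] or (protein or codon.translate()).identifiers[0]
    ref_map_protein = seqio.build_reference_map(protein, ref_id) if protein else None

    if "rca" in stages:
        p = config["rca"]
        log.info("rca: window=%s threshold=%s K=%s", p["window"], p["threshold"], p["K"])
        tree = _get_tree(config, protein, jtt_model())
        write_newick(tree, outdir / "rca_tree.nwk")
        art.profile = rca_mod.conservation_profile(
            protein, tree, jtt_model(), K=int(p["K"]), window=int(p["window"]),
            threshold=float(p["threshold"]), ref_map=ref_map_protein)
        _write_rca(art.profile, ref_map_protein, outdir)
        art.summary["rca_regions"] = len(art.profile.regions)

    rel_fit = None
    if "rel" in stages or "bgm" in stages:
        preset = config["rel"]["constraints"]
        constraints = (rel_mod.PRESETS[preset] if isinstance(preset, str)
                       else rel_mod.constraint_set_from_dict("custom", preset))
        nuc_model = gtr_model({}, rel_mod.fit.empirical_nucleotide_frequencies(codon.base))
        tree = _get_tree(config, codon.base, nuc_model)
        trans = codon.translate()
        ref_map_codon = seqio.build_reference_map(trans, ref_id) \
            if ref_id in trans.identifiers else None
        p = config["rel"]
        log.info("rel: constraints=%s strong=%s weak=%s", constraints.name,
                 p["strong"], p["weak"])
        rel_fit = rel_mod.fit_rel(
            codon, tree, constraints, freq_method=p["frequencies"],
            n_starts=int(p["starts"]), maxfev=int(p["maxfev"]),
            ref_map=ref_map_codon, strong_threshold=float(p["strong"]),
            weak_threshold=float(p["weak"]))
        art.rel_fit = rel_fit
        if "rel" in stages:
            _write_rel(rel_fit, outdir)
            cats = [s.category for s in rel_fit.per_site]
            art.summary["rel_strong"] = cats.count("strong")
            art.summary["rel_weak"] = cats.count("weak")
            art.summary["rel_positive_class_ratios"] = (
                rel_fit.grid.positive_class_ratios()
                if rel_fit.selection_gate_passed else [])

    if "bgm" in stages:
        p = config["bgm"]
        log.info("bgm: min_count=%s pp=%s chain=%s", p["min_count"], p["pp"],
                 p["chain_length"])
        Qs, pi = bgm_mod.collapsed_site_rate_matrices(rel_fit)
        recon = bgm_mod.joint_ancestral_codons(
            rel_fit.tree, codon, Q_stack=Qs, frequencies=pi,
            scale=1.0)
        smap = bgm_mod.substitution_map(rel_fit.tree, codon, recon,
                                        site_labels=rel_fit.site_labels)
        smap = bgm_mod.filter_sites(smap, int(p["min_count"]))
        if len(smap.sites) < 2:
            log.warning("bgm: fewer than 2 sites pass the non-synonymous "
                        "count filter; skipping network fit")
        else:
            art.network = bgm_mod.bgm_fit(
                smap, max_parents=int(p["max_parents"]),
                chain_length=int(p["chain_length"]),
                burn_in=int(p["burn_in"]), seed=int(config["seed"]))
            pairs, groups = bgm_mod.call_coevolving(art.network, float(p["pp"]))
            art.network.called_pairs = pairs
            art.network.groups = groups
            _write_bgm(art.network, outdir)
            art.summary["bgm_pairs"] = len(pairs)
            art.summary["bgm_groups"] = len(groups)

    art.report = cross_annotate(
        art.profile.regions if art.profile else [],
        rel_fit.per_site if rel_fit else [],
        art.network.groups if art.network else [],
        ref_map_protein, profile=art.profile)
    art.report.to_csv(outdir / "site_report.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(art.summary, fh, indent=2, default=str)
    log.info("summary: %s", art.summary)
    return art


def cross_annotate(rca_regions, rel_sites, bgm_groups, ref_map,
                   profile=None) -> pd.DataFrame:
    """Join stage outputs on reference residue numbering.

    Regions are closed intervals; a site equal to a region boundary is inside.
    """
    rel_by_site = {s.site: s for s in rel_sites}
    group_by_site = {}
    for gi, group in enumerate(bgm_groups, start=1):
        for site in group:
            group_by_site[site] = gi

    if ref_map is not None:
        residues = sorted(ref_map.residue_to_column)
    else:
        residues = sorted(set(rel_by_site) | set(group_by_site) |
                          {r for reg in rca_regions for r in reg})

    rows = []
    for res in residues:
        region_id = next((i + 1 for i, (a, b) in enumerate(rca_regions)
                          if a <= res <= b), None)
        sel = rel_by_site.get(res)
        col = ref_map.column(res) if ref_map is not None else None
        rows.append({
            "residue": res,
            "s_score": (float(profile.s_scores[col - 1])
                        if profile is not None and col else math.nan),
            "w_score": (float(profile.w_scores[col - 1])
                        if profile is not None and col else math.nan),
            "in_region": region_id is not None,
            "region_id": region_id,
            "rel_posterior": sel.posterior_positive if sel else math.nan,
            "rel_bayes_factor": sel.bayes_factor if sel else math.nan,
            "rel_category": sel.category if sel else "",
            "coevolution_group": group_by_site.get(res),
        })
    df = pd.DataFrame(rows)
    n_sel_in_regions = int(((df.rel_category.isin(["strong", "weak"]))
                            & df.in_region).sum())
    df.attrs["selected_sites_in_regions"] = n_sel_in_regions
    return df


def _write_rca(profile, ref_map, outdir: Path) -> None:
    rows = []
    for k, col in enumerate(profile.columns):
        local_col = k + 1  # profile.columns carries original coordinates
        res = ref_map.residue(local_col) if ref_map else int(col)
        in_region = any(a <= (res if res else -1) <= b for a, b in profile.regions)
        rows.append({"column": int(col), "reference_residue": res,
                     "s": float(profile.s_scores[k]),
                     "w": float(profile.w_scores[k]), "in_region": in_region})
    pd.DataFrame(rows).to_csv(outdir / "rca_profile.tsv", sep="\t", index=False)
    with open(outdir / "rca_regions.json", "w") as fh:
        json.dump({"alpha": profile.alpha, "K": profile.K,
                   "regions": profile.regions}, fh, indent=2)


def _write_rel(fit, outdir: Path) -> None:
    pd.DataFrame([{
        "position": s.site, "posterior_probability": s.posterior_positive,
        "bayes_factor": s.bayes_factor, "category": s.category,
    } for s in fit.per_site]).to_csv(outdir / "rel_sites.tsv", sep="\t",
                                     index=False)
    summary = {
        "log_likelihood": fit.log_likelihood,
        "dn_values": fit.grid.dn_values.tolist(),
        "ds_values": fit.grid.ds_values.tolist(),
        "dn_values_raw": fit.grid.dn_values_raw.tolist(),
        "ds_values_raw": fit.grid.ds_values_raw.tolist(),
        "weights": fit.grid.weights.tolist(),
        "positive_class_ratios": fit.grid.positive_class_ratios(),
        "prior_positive": fit.prior_positive,
        "nucleotide_rates": fit.nucleotide_mles,
        "constraints": fit.constraints.name,
        "branch_scale": fit.branch_scale,
        "heterogeneity_gain": fit.heterogeneity_gain,
        "selection_gate_passed": fit.selection_gate_passed,
        "converged": fit.converged,
        "starts": fit.start_log,
    }
    with open(outdir / "rel_fit.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def _write_bgm(network, outdir: Path) -> None:
    pd.DataFrame([{"position_1": a, "position_2": b, "posterior_probability": p}
                  for a, b, p in network.called_pairs]).to_csv(
        outdir / "bgm_pairs.tsv", sep="\t", index=False)
    with open(outdir / "bgm_network.json", "w") as fh:
        json.dump({
            "edge_posterior": {f"{a}-{b}": p for (a, b), p
                               in sorted(network.edge_posterior.items())},
            "groups": [sorted(g) for g in network.groups],
            "diagnostics": network.mcmc_diagnostics,
        }, fh, indent=2)
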