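"""End-to-end orchestration: scan → tune → reconstruct → select → date → converge.

Each stage reads its inputs from the previous stage's in-memory results,
writes a TSV under the output directory, and records status in a
:class:`RunReport`.  A stage failure halts its dependents but not independent
stages, and all outputs are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import tomllib
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .ancestral import detect_convergence, enumerate_substitutions, marginal_ml_reconstruction
from .dating import categorize_branches, resolve_mixed
from .io import read_codon_alignment, read_newick, translate
from .orf import place_lesions, scan_orf
from .selection import CodonModelSpec, fit_model, lrt, strip_indel_codons
from .simulate import name_nodes
from .tuning import LambdaTable, TuningSiteSet, ancestral_tuning

ALL_STAGES = ("scan", "tune", "ancestral", "dnds", "date", "converge")
_STAGE_DEPS = {
    "scan": (),
    "tune": ("ancestral",),
    "ancestral": (),
    "dnds": (),
    "date": ("scan", "dnds"),
    "converge": ("ancestral",),
}


@dataclass
class PipelineConfig:
    alignment_path: str
    tree_path: str
    out_dir: str
    tree_units: str = "My"
    stages: tuple = ALL_STAGES
    seed: int = 0
    reference_taxon: Optional[str] = None  # ORF scan polarity reference
    gene: str = "LWS"
    # reference position -> 1-based aa column in the alignment's translation
    tuning_site_columns: dict = field(default_factory=dict)
    model_battery: tuple = ("M0", "M1a", "M2a", "M7", "M8")
    foreground_tags: tuple = ()  # adds a two-ratio model per tag
    tip_tags: dict = field(default_factory=dict)
    convergence_pair: Optional[tuple] = None  # branch names
    fit_kwargs: dict = field(default_factory=dict)
    rate_scale: float = 0.01  # subs/site/My: initial branch lengths for fits

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw["tuning_site_columns"] = {
            int(k): v for k, v in raw.get("tuning_site_columns", {}).items()
        }
        for key in ("stages", "model_battery", "foreground_tags", "convergence_pair"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.alignment_path, self.tree_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


@dataclass
class StageStatus:
    name: str
    status: str  # {ok, failed, skipped, skipped-dependency}
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    detail: str = ""


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)  # path -> sha256

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": s.name, "status": s.status,
                 "outputs": ";".join(s.outputs), "detail": s.detail}
                for s in self.stages.values()
            ]
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, report: RunReport, seed: int) -> str:
    with open(path, "w") as fh:
        fh.write(f"# opsinphylo {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    report.manifest[str(path)] = _sha256(path)
    return str(path)


def render_model_table(fits: list, lrts: Optional[dict] = None) -> pd.DataFrame:
    """Model-fit table with the layout of a selection-test summary:
    (Model, omega, lnL, NP, Models Compared, 2Delta, P-value)."""
    lrts = lrts or {}
    rows = []
    for i, fit in enumerate(fits, start=1):
        est = fit.estimates
        if fit.model_id == "M0":
            omega = f"omega = {est['omega']:.4f}"
        elif fit.model_id == "two-ratio":
            omega = (
                f"omega1 = {est['omega_foreground']:.4f}; "
                f"omega2 = {est['omega_background']:.4f}"
            )
        elif fit.model_id in {"free-ratio"}:
            omega = "variable by branch"
        elif "class_omegas" in est:
            omega = "; ".join(
                f"p{k} = {w:.4f} (omega{k} = {o:.4f})"
                for k, (o, w) in enumerate(
                    zip(est["class_omegas"], est["class_weights"])
                )
            )
        else:
            omega = "; ".join(
                f"{k} = {v:.4f}" for k, v in est.items() if k.startswith("omega")
            )
        row = {
            "Model": f"{i}. {fit.model_id}",
            "omega": omega,
            "lnL": round(fit.lnL, 2),
            "NP": fit.np,
            "Models Compared": "",
            "2Delta": "",
            "P-value": "",
        }
        key = fit.model_id
        if key in lrts:
            other_idx, res = lrts[key]
            row["Models Compared"] = f"{other_idx} vs. {i}"
            row["2Delta"] = round(res.twice_delta, 2)
            row["P-value"] = f"{res.p_value:.3g}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    report = RunReport(config_hash=cfg_hash, seed=config.seed)

    alignment = read_codon_alignment(config.alignment_path)
    tree = name_nodes(read_newick(config.tree_path, units=config.tree_units))
    # fits want branch lengths in expected subs/site; start calibrated trees
    # at a plausible molecular scale and let the optimizer refine
    fit_base = tree.copy()
    if config.tree_units == "My":
        for node in fit_base.preorder():
            node.length *= config.rate_scale
        fit_base.units = "subs"

    results: dict = {}

    def run_stage(name, fn):
        if name not in config.stages:
            report.stages[name] = StageStatus(name, "skipped")
            return
        for dep in _STAGE_DEPS[name]:
            dep_status = report.stages.get(dep)
            if dep_status is None or dep_status.status != "ok":
                report.stages[name] = StageStatus(
                    name, "skipped-dependency", detail=f"requires stage {dep!r}"
                )
                return
        try:
            outputs = fn()
            report.stages[name] = StageStatus(name, "ok", outputs=outputs)
        except Exception as exc:  # noqa: BLE001 — reported, not swallowed silently
            report.stages[name] = StageStatus(
                name, "failed", detail=f"{exc}\n{traceback.format_exc(limit=3)}"
            )

    # -- scan ---------------------------------------------------------------
    def stage_scan():
        calls = scan_orf(alignment, reference_taxon=config.reference_taxon)
        results["calls"] = calls
        rows = [
            {
                "taxon": c.taxon, "status": c.status, "kind": l.kind,
                "exon": l.exon_index, "codon_column": l.codon_column,
                "length_nt": l.length_nt, "frameshift": l.causes_frameshift,
            }
            for c in calls
            for l in (c.lesions or [None])
            if l is not None
        ] or [
            {"taxon": c.taxon, "status": c.status, "kind": "", "exon": "",
             "codon_column": "", "length_nt": "", "frameshift": ""}
            for c in calls
        ]
        status_rows = [{"taxon": c.taxon, "status": c.status} for c in calls]
        p1 = _write(pd.DataFrame(rows), out_dir / "lesions.tsv", report, config.seed)
        p2 = _write(
            pd.DataFrame(status_rows), out_dir / "functionality.tsv", report, config.seed
        )
        return [p1, p2]

    # -- ancestral ----------------------------------------------------------
    def stage_ancestral():
        stripped, _ = strip_indel_codons(alignment)
        aa = {t: translate(stripped.row(t)) for t in stripped.ids}
        states = marginal_ml_reconstruction(fit_base, aa)
        results["ancestral"] = states
        results["aa_alignment"] = aa
        df = pd.DataFrame(
            [{"node": k, "sequence": v} for k, v in sorted(states.states.items())]
        )
        return [_write(df, out_dir / "ancestral_sequences.tsv", report, config.seed)]

    # -- tune ---------------------------------------------------------------
    def stage_tune():
        states = results["ancestral"]
        sites = (
            TuningSiteSet.lws() if config.gene == "LWS" else TuningSiteSet.sws1()
        )
        profiles = ancestral_tuning(
            tree, states, config.tuning_site_columns, gene=config.gene,
            table=LambdaTable(), sites=sites,
        )
        rows = [
            {
                "node": name, "label": p.taxon_or_node, "haplotype": p.haplotype,
                "lambda_max_nm": p.lambda_max, "class": p.spectral_class,
                "provenance": p.provenance,
            }
            for name, p in sorted(profiles.items())
        ]
        return [_write(pd.DataFrame(rows), out_dir / "tuning.tsv", report, config.seed)]

    # -- dnds ---------------------------------------------------------------
    def stage_dnds():
        stripped, removal_log = strip_indel_codons(alignment)
        fits, lrt_map = [], {}
        fit_kwargs = dict(config.fit_kwargs)
        m0 = None
        battery = list(config.model_battery) + [
            ("two-ratio", tag) for tag in config.foreground_tags
        ]
        for k, entry in enumerate(battery, start=1):
            if isinstance(entry, tuple):
                model, tag = entry
                from .selection import label_branches

                fit_tree = label_branches(fit_base, tag, config.tip_tags)
                spec = CodonModelSpec(model, foreground_tag=tag, seed=config.seed,
                                      **fit_kwargs)
            else:
                model, fit_tree = entry, fit_base
                spec = CodonModelSpec(model, seed=config.seed, **fit_kwargs)
            fit = fit_model(stripped, fit_tree, spec)
            fits.append(fit)
            if model == "M0":
                m0 = (k, fit)
        by_id = {f.model_id: (i + 1, f) for i, f in enumerate(fits)}
        pairings = [("M2a", "M1a"), ("M8", "M7")]
        for gen, res in pairings:
            if gen in by_id and res in by_id:
                lrt_map[gen] = (by_id[res][0], lrt(by_id[gen][1], by_id[res][1]))
        if m0 is not None:
            for f in fits:
                if f.model_id in {"two-ratio", "free-ratio"}:
                    lrt_map[f.model_id] = (m0[0], lrt(f, m0[1]))
        results["fits"] = fits
        table = render_model_table(fits, lrt_map)
        p1 = _write(table, out_dir / "model_fits.tsv", report, config.seed)
        p2 = _write(
            pd.DataFrame(removal_log, columns=["codon_column", "reason"]),
            out_dir / "stripped_codons.tsv", report, config.seed,
        )
        return [p1, p2]

    # -- date ---------------------------------------------------------------
    def stage_date():
        calls = results["calls"]
        origins = place_lesions(calls, tree)
        categories = categorize_branches(tree, origins)
        cat_map = {c.branch: c.category for c in categories}
        present = sorted({c.category for c in categories})
        stripped, _ = strip_indel_codons(alignment)
        omegas = {}
        if "mixed" in present:
            spec = CodonModelSpec(
                "labels", branch_label_map=cat_map, seed=config.seed,
                **config.fit_kwargs,
            )
            fit = fit_model(stripped, fit_base, spec)
            omegas = {
                lab: fit.estimates[f"omega_{lab}"] for lab in present
            }
        estimates = resolve_mixed(categories, omegas, tree)
        rows = [
            {
                "lineage": e.lineage, "T_My": e.T, "omega_f": e.omega_f,
                "omega_m": e.omega_m, "T_p_My": e.T_p, "T_f_My": e.T_f,
                "loss_date_Ma": e.loss_date_ma, "clamped": e.clamped,
                "note": e.note,
            }
            for e in estimates
        ]
        cat_rows = [{"branch": c.branch, "category": c.category} for c in categories]
        p1 = _write(pd.DataFrame(cat_rows), out_dir / "branch_categories.tsv",
                    report, config.seed)
        p2 = _write(pd.DataFrame(rows), out_dir / "loss_dates.tsv", report, config.seed)
        return [p1, p2]

    # -- converge -----------------------------------------------------------
    def stage_converge():
        states = results["ancestral"]
        events = enumerate_substitutions(states, tree)
        ev_df = pd.DataFrame(
            [
                {"branch": e.branch, "site": e.site, "from": e.from_state,
                 "to": e.to_state}
                for e in events
            ]
        )
        outputs = [_write(ev_df, out_dir / "substitutions.tsv", report, config.seed)]
        if config.convergence_pair:
            rep = detect_convergence(events, tuple(config.convergence_pair), tree)
            conv_df = pd.DataFrame(
                [
                    {"branch_a": rep.branch_pair[0], "branch_b": rep.branch_pair[1],
                     "convergent_sites": ";".join(map(str, rep.convergent_sites)),
                     "divergent_sites": ";".join(map(str, rep.divergent_sites)),
                     "n_convergent": rep.n_convergent,
                     "n_divergent": rep.n_divergent}
                ]
            )
            outputs.append(
                _write(conv_df, out_dir / "convergence.tsv", report, config.seed)
            )
        return outputs

    run_stage("scan", stage_scan)
    run_stage("ancestral", stage_ancestral)
    run_stage("tune", stage_tune)
    run_stage("dnds", stage_dnds)
    run_stage("date", stage_date)
    run_stage("converge", stage_converge)

    _write(report.to_frame(), out_dir / "run_report.tsv", report, config.seed)
    return report
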