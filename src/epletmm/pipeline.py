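"""Config-driven end-to-end orchestration.

typing -> imputation -> mismatch -> categories -> events -> ROC/survival ->
report.  All outputs are plain CSV/JSON, written only after every stage has
succeeded so a failed run leaves no partial outputs.  Reports carry the
package version, seed, and a config hash, and contain no timestamps so
fixed-seed runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    apply_cohort_filters,
    cox_fit,
    define_dndsa_events,
    derive_two_stage_thresholds,
    flag_early_dsa,
    km_estimate,
    load_cohort_records,
    logrank_test,
    roc_auc,
)
from .errors import ContractError, CoxError, EpletMMError, PipelineError
from .mismatch import attribute_dsa_to_molecules, recipient_mismatch_summary
from .registry import (
    HaplotypeFrequencyTable,
    enumerate_molecules,
    impute_two_field,
    load_eplet_registry,
    parse_typing_table,
)
from .risk import BUILTIN_SCHEMES, CategoryScheme, RiskCategory, classify


@dataclass
class PipelineConfig:
    registry: str
    typings: str
    outcomes: str
    detections: str
    output_dir: str
    frequencies: str | None = None
    seed: int = 0
    imputation_enabled: bool = True
    mfi_cutoff: float = 500.0
    memory_window_days: float = 14.0
    schemes: list[CategoryScheme] = field(
        default_factory=lambda: [BUILTIN_SCHEMES["wiebe"], BUILTIN_SCHEMES["nucot"]]
    )
    derive_thresholds: bool = True
    cox_scheme: str = "nucot"

    def __post_init__(self):
        if self.mfi_cutoff <= 0:
            raise ContractError("MFI cutoff must be positive")
        if self.memory_window_days < 0:
            raise ContractError("memory window must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        schemes = [
            CategoryScheme.from_dict(d) if isinstance(d, dict) else BUILTIN_SCHEMES[d]
            for d in raw.get("schemes", ["wiebe", "nucot"])
        ]
        base = os.path.dirname(os.path.abspath(path))

        def _resolve(p):
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        return cls(
            registry=_resolve(raw["registry"]),
            typings=_resolve(raw["typings"]),
            outcomes=_resolve(raw["outcomes"]),
            detections=_resolve(raw["detections"]),
            output_dir=_resolve(raw.get("output_dir", "out")),
            frequencies=_resolve(raw.get("frequencies")),
            seed=int(raw.get("seed", 0)),
            imputation_enabled=bool(raw.get("imputation", {}).get("enabled", True)),
            mfi_cutoff=float(raw.get("events", {}).get("mfi_cutoff", 500)),
            memory_window_days=float(raw.get("events", {}).get("memory_window_days", 14)),
            schemes=schemes,
            derive_thresholds=bool(raw.get("derive_thresholds", True)),
            cox_scheme=str(raw.get("cox", {}).get("scheme", "nucot")),
        )

    def to_dict(self) -> dict:
        return {
            "registry": self.registry,
            "typings": self.typings,
            "outcomes": self.outcomes,
            "detections": self.detections,
            "frequencies": self.frequencies,
            "seed": self.seed,
            "imputation_enabled": self.imputation_enabled,
            "mfi_cutoff": self.mfi_cutoff,
            "memory_window_days": self.memory_window_days,
            "schemes": [s.to_dict() for s in self.schemes],
            "derive_thresholds": self.derive_thresholds,
            "cox_scheme": self.cox_scheme,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    """Decorator-free stage wrapper: re-raise any error tagged with the stage."""

    class _Ctx:
        def __init__(self, n):
            self.n = n

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(self.n, str(exc)) from exc
            return False

    return _Ctx(name)


def score_typings(registry, typings, freq=None):
    """Impute (when needed and possible) and score every pair.

    Returns ``(summaries, donor_molecules_by_pair)``.
    """
    by_pair: dict[str, dict[str, object]] = {}
    for t in typings:
        by_pair.setdefault(t.pair_id, {})[t.role] = t
    summaries = []
    donor_mols = {}
    for pair_id in sorted(by_pair):
        members = by_pair[pair_id]
        if "donor" not in members or "recipient" not in members:
            raise ContractError(f"pair {pair_id}: needs one donor and one recipient")
        donor, recipient = members["donor"], members["recipient"]
        if freq is not None:
            donor = impute_two_field(donor, freq, donor.ethnicity)
            recipient = impute_two_field(recipient, freq, recipient.ethnicity)
        summaries.append(recipient_mismatch_summary(donor, recipient, registry))
        donor_mols[pair_id] = enumerate_molecules(donor, registry)
    return summaries, donor_mols


def _molecule_level_data(summaries, donor_mols, records_by_pair, mfi_cutoff, memory_days):
    """Per-molecule scores plus dnDSA-against-this-molecule labels."""
    rows = {"DR": [], "DQ": []}
    for summ in summaries:
        pid = summ.pair_id
        rec = records_by_pair.get(pid)
        mols = donor_mols[pid]
        hit_ids: set[str] = set()
        if rec is not None:
            for det in rec.detections:
                if det.mfi is None or det.mfi < mfi_cutoff or det.day <= memory_days:
                    continue
                hit_ids.update(attribute_dsa_to_molecules(det.specificity, mols))
        counts = {m.molecule_id: m for m in mols}
        for mm in summ.molecule_mismatches:
            cls = "DR" if mm.kind == "DR_beta" else "DQ"
            rows[cls].append(
                {
                    "pair_id": pid,
                    "molecule_id": mm.molecule_id,
                    "score": mm.count,
                    "label": int(mm.molecule_id in hit_ids),
                }
            )
    return {
        cls: pd.DataFrame(r, columns=["pair_id", "molecule_id", "score", "label"])
        for cls, r in rows.items()
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict and writes outputs."""
    report: dict = {
        "version": __version__,
        "report_schema": 1,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    with _stage("load"):
        registry = load_eplet_registry(config.registry)
        typings = parse_typing_table(config.typings)
        records = load_cohort_records(config.outcomes, config.detections)
        freq = None
        if config.imputation_enabled and config.frequencies:
            freq = HaplotypeFrequencyTable.from_csv(config.frequencies)

    with _stage("score"):
        summaries, donor_mols = score_typings(registry, typings, freq)
        summ_by_pair = {s.pair_id: s for s in summaries}

    with _stage("filters"):
        for rec in records:
            if rec.pair_id in donor_mols:
                rec.flags["dsa_within_14d"] = flag_early_dsa(
                    rec, donor_mols[rec.pair_id], config.mfi_cutoff,
                    config.memory_window_days,
                )
        retained, tally = apply_cohort_filters(records)
        report["n_input"] = len(records)
        report["n_retained"] = len(retained)
        report["exclusions"] = tally

    with _stage("events"):
        records_by_pair = {r.pair_id: r for r in retained}
        event_rows = []
        for rec in retained:
            ev = define_dndsa_events(
                rec, donor_mols[rec.pair_id], config.mfi_cutoff,
                config.memory_window_days,
            )
            combined_event = ev["DR"].event or ev["DQ"].event
            combined_time = min(
                (e.time_years for e in ev.values() if e.event),
                default=rec.follow_up_years,
            )
            event_rows.append(
                {
                    "pair_id": rec.pair_id,
                    "dr_event": int(ev["DR"].event),
                    "dr_time_years": ev["DR"].time_years,
                    "dq_event": int(ev["DQ"].event),
                    "dq_time_years": ev["DQ"].time_years,
                    "event": int(combined_event),
                    "time_years": combined_time,
                }
            )
        events_df = pd.DataFrame(event_rows)
        report["n_dndsa"] = int(events_df["event"].sum()) if len(events_df) else 0

    with _stage("categories"):
        retained_summaries = [summ_by_pair[r.pair_id] for r in retained]
        cat_df = pd.DataFrame(
            {
                "pair_id": [s.pair_id for s in retained_summaries],
                "dr_max": [s.dr_max for s in retained_summaries],
                "dq_max": [s.dq_max for s in retained_summaries],
            }
        )
        report["categories"] = {}
        for scheme in config.schemes:
            cat_df[f"category_{scheme.name}"] = [
                classify(s.dr_max, s.dq_max, scheme).name for s in retained_summaries
            ]
            counts = cat_df[f"category_{scheme.name}"].value_counts().to_dict()
            n = len(cat_df)
            report["categories"][scheme.name] = {
                c.name: {
                    "count": int(counts.get(c.name, 0)),
                    "proportion": counts.get(c.name, 0) / n if n else 0.0,
                }
                for c in RiskCategory
            }

    with _stage("roc"):
        mol_data = _molecule_level_data(
            retained_summaries, donor_mols, records_by_pair,
            config.mfi_cutoff, config.memory_window_days,
        )
        report["roc"] = {}
        for cls in ("DR", "DQ"):
            df = mol_data[cls]
            if len(df) and df["label"].nunique() == 2:
                roc = roc_auc(df["score"], df["label"])
                report["roc"][cls] = {
                    "auc": roc.auc,
                    "n_molecules": int(len(df)),
                    "n_positive": int(df["label"].sum()),
                }
            else:
                report["roc"][cls] = {"auc": None, "note": "single-class labels"}

    derived_scheme = None
    if config.derive_thresholds:
        with _stage("derive_thresholds"):
            low_scheme = config.schemes[0]
            try:
                derived_scheme = derive_two_stage_thresholds(
                    mol_data, retained_summaries, low_scheme, name="derived"
                )
                report["derived_scheme"] = derived_scheme.to_dict()
            except EpletMMError as e:
                report["derived_scheme"] = {"error": str(e)}

    with _stage("survival"):
        merged = events_df.merge(cat_df, on="pair_id")
        report["survival"] = {}
        km_tables = {}
        for scheme in config.schemes:
            col = f"category_{scheme.name}"
            entry = {"km": {}, "logrank": {}}
            frames = []
            for cat in ("LOW", "INTERMEDIATE", "HIGH"):
                grp = merged[merged[col] == cat]
                if len(grp) == 0:
                    continue
                curve = km_estimate(grp["time_years"], grp["event"])
                f = curve.to_frame()
                f.insert(0, "category", cat)
                frames.append(f)
                entry["km"][cat] = {
                    "n": int(len(grp)),
                    "events": int(grp["event"].sum()),
                }
            for a, b in (("LOW", "INTERMEDIATE"), ("INTERMEDIATE", "HIGH"), ("LOW", "HIGH")):
                ga, gb = merged[merged[col] == a], merged[merged[col] == b]
                if len(ga) and len(gb):
                    stat, p = logrank_test(
                        ga["time_years"], ga["event"], gb["time_years"], gb["event"]
                    )
                    entry["logrank"][f"{a.lower()}_vs_{b.lower()}"] = {
                        "statistic": stat, "p": p,
                    }
            km_tables[scheme.name] = (
                pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            )
            report["survival"][scheme.name] = entry

    with _stage("cox"):
        scheme = next(
            (s for s in config.schemes if s.name == config.cox_scheme),
            config.schemes[-1],
        )
        col = f"category_{scheme.name}"
        report["cox"] = _fit_adjusted_cox(merged, col)

    with _stage("write"):
        os.makedirs(config.output_dir, exist_ok=True)
        written = []
        try:
            def _path(name):
                p = os.path.join(config.output_dir, name)
                written.append(p)
                return p

            cat_df.to_csv(_path("summary.csv"), index=False)
            events_df.to_csv(_path("events.csv"), index=False)
            for name, table in km_tables.items():
                table.to_csv(_path(f"km_{name}.csv"), index=False)
            mol_rows = pd.concat(
                [mol_data["DR"].assign(locus_class="DR"),
                 mol_data["DQ"].assign(locus_class="DQ")],
                ignore_index=True,
            )
            mol_rows.to_csv(_path("molecules.csv"), index=False)
            with open(_path("report.json"), "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
        except Exception:
            for p in written:
                if os.path.exists(p):
                    os.remove(p)
            raise
    return report


def _fit_adjusted_cox(merged: pd.DataFrame, category_col: str) -> dict:
    """Adjusted Cox model: risk category + CNI + anti-metabolite.

    Degenerate covariates (constant in small cohorts) are dropped one at a
    time; the report records which model was actually fit.
    """
    df = merged.copy()
    cat_levels = [
        c for c in ("LOW", "INTERMEDIATE", "HIGH") if (df[category_col] == c).any()
    ]
    attempts = []
    covars = [category_col]
    categorical = {category_col: cat_levels}
    if "cni" in df.columns and df["cni"].nunique() > 1:
        covars.append("cni")
        categorical["cni"] = ["tacrolimus", "cyclosporine"]
    if "antimetabolite" in df.columns and df["antimetabolite"].nunique() > 1:
        am_levels = [
            a for a in ("azathioprine", "mycophenolate", "none")
            if (df["antimetabolite"] == a).any()
        ]
        covars.append("antimetabolite")
        categorical["antimetabolite"] = am_levels
    while covars:
        try:
            fit = cox_fit(df, "time_years", "event", covars,
                          {k: v for k, v in categorical.items() if k in covars})
            break
        except (CoxError, ContractError) as e:
            attempts.append(f"{covars}: {e}")
            covars = covars[:-1]
    else:
        return {"error": "no Cox model could be fit", "attempts": attempts}
    out = {
        "covariates": covars,
        "terms": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in fit.summary.iterrows()
        },
        "log_likelihood": fit.log_likelihood,
    }
    if len(cat_levels) >= 2 and category_col in covars:
        contrasts = {}
        pairs = [(a, b) for i, b in enumerate(cat_levels) for a in cat_levels[i + 1:]]
        for a, b in pairs:
            contrasts[f"{a.lower()}_vs_{b.lower()}"] = {
                k: float(v) for k, v in fit.contrast(category_col, a, b).items()
            }
        out["category_contrasts"] = contrasts
    if attempts:
        out["dropped"] = attempts
    return out
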