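"""End-to-end pipeline over a directory of gene families.

For each family (an ML tree plus a file of bootstrap replicate trees) the
pipeline: detects LECA clades (flagging and optionally pruning prokaryotic
intruders), reduces each clade to k representatives by least-squares rooting
and iterative pruning, restricts every tree to the representatives plus all
non-clade leaves (emulating re-inferred representative trees), discards clades
whose representative-set monophyly has no more than the retention threshold of
bootstrap support, classifies the retained clades on the ML tree and across
all replicates, and computes NBS/SGS. Results are emitted as one table row
per LECA clade plus a per-configuration summary.

Every input family is accounted for in exactly one of: report rows, the
"no LECA clade" log, or the "ambiguous (discarded)" log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .configurations import (ARCHAEAL_DOMAIN_RELATED, BACTERIAL_DOMAIN_RELATED,
                             GROUP_RELATED, PARAPHYLETIC, THREE_DOMAIN, UNCLEAR,
                             ConfigurationError, GroupThresholds,
                             bootstrap_configuration_profile,
                             classify_configuration)
from .leca import detect_leca_clades
from .sampling import sample_representatives
from .support import (clade_support, monophyly_support, near_universal_filter)
from .taxonomy import TaxonomyMap, read_taxonomy
from .trees import (GeneTree, NotAClanError, leafset_str,
                    read_bootstrap_trees, read_newick)

logger = logging.getLogger(__name__)

# Display order of configuration classes in reports (most to least specific
# bacterial signal, then archaeal, then unresolved).
CLASS_ORDER = {GROUP_RELATED: 0, BACTERIAL_DOMAIN_RELATED: 1, THREE_DOMAIN: 2,
               ARCHAEAL_DOMAIN_RELATED: 3, UNCLEAR: 4, PARAPHYLETIC: 5}


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    k_representatives: int = 10
    retention_threshold: float = 50.0   # strict: support must exceed this
    max_intruder_size: int = 2
    auto_prune: bool = True
    near_universal_fraction: float = 0.9
    thresholds: GroupThresholds = field(default_factory=GroupThresholds.default)
    reference_families: frozenset = frozenset()  # e.g. organelle-encoded markers

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        thresholds = GroupThresholds.default()
        if "thresholds" in data:
            thresholds = GroupThresholds.from_yaml(path) if isinstance(
                data["thresholds"], str) else thresholds.with_overrides(
                {name: (int(v["sampled"]), v["threshold"])
                 for name, v in data["thresholds"].items()})
        try:
            return PipelineConfig(
                k_representatives=int(data.get("k_representatives", 10)),
                retention_threshold=float(data.get("retention_threshold", 50.0)),
                max_intruder_size=int(data.get("max_intruder_size", 2)),
                auto_prune=bool(data.get("auto_prune", True)),
                near_universal_fraction=float(
                    data.get("near_universal_fraction", 0.9)),
                thresholds=thresholds,
                reference_families=frozenset(
                    data.get("reference_families", ())),
            )
        except (TypeError, ValueError) as exc:
            raise PipelineError(f"invalid pipeline config: {exc}") from exc


@dataclass
class CladeReportRow:
    cluster_id: str
    clade_index: int
    n_leaves: int
    rules: str
    representatives: str
    ml_config: str
    ml_group: str
    modal_config: str
    modal_group: str
    frequencies: str
    group_fractions: str
    nbs: float
    sgs_percent: float
    g_ml: str
    monophyly_support: float
    near_universal: bool
    archaea_monophyly: float
    bacteria_monophyly: float
    reference_flag: bool
    intruders_removed: str


@dataclass
class PipelineResult:
    rows: list
    no_leca: list          # (family_id, reason)
    ambiguous: list        # (family_id, clade_index, support)
    n_families: int

    @property
    def report(self) -> pd.DataFrame:
        frame = pd.DataFrame([vars(r) for r in self.rows])
        if frame.empty:
            return frame
        order = frame["ml_config"].map(CLASS_ORDER)
        frame = frame.assign(_order=order).sort_values(
            ["_order", "ml_group", "nbs"],
            ascending=[True, True, False]).drop(columns="_order")
        return frame.reset_index(drop=True)

    @property
    def summary(self) -> pd.DataFrame:
        """Counts of LECA clades per configuration, under both the ML-tree
        and the modal-bootstrap-configuration criterion."""
        def label(config, group):
            return f"{config}({group})" if group else config

        counts: dict[str, list[int]] = {}
        for row in self.rows:
            for i, key in enumerate((label(row.ml_config, row.ml_group),
                                     label(row.modal_config, row.modal_group))):
                counts.setdefault(key, [0, 0])[i] += 1
        frame = pd.DataFrame(
            [(k, v[0], v[1]) for k, v in sorted(counts.items())],
            columns=["configuration", "n_ml", "n_modal"])
        return frame


def _serialize_freqs(freqs: dict) -> str:
    parts = []
    for (kind, group), f in sorted(freqs.items(), key=lambda kv: -kv[1]):
        name = f"{kind}({group})" if group else kind
        parts.append(f"{name}={f:.3f}")
    return ";".join(parts)


def discover_families(input_dir) -> list[tuple[str, Path, Path | None]]:
    """Families in a directory: ``<id>.ml.nwk`` plus optional ``<id>.boot.nwk``."""
    root = Path(input_dir)
    out = []
    for ml in sorted(root.glob("*.ml.nwk")):
        fam = ml.name[: -len(".ml.nwk")]
        boot = root / f"{fam}.boot.nwk"
        out.append((fam, ml, boot if boot.exists() else None))
    return out


def analyze_family(family_id: str, ml_tree: GeneTree,
                   replicates: list | None, tax: TaxonomyMap,
                   config: PipelineConfig) -> tuple[list, list, str | None]:
    """Analysis of one family; returns (rows, ambiguous, no_leca_reason)."""
    missing = tax.missing(ml_tree.leaves)
    if missing:
        raise PipelineError(
            f"{family_id}: leaves absent from taxonomy: {missing}")

    clades, work = detect_leca_clades(
        ml_tree, tax, family_id,
        max_intruder_size=config.max_intruder_size,
        auto_prune=config.auto_prune)
    leca = [c for c in clades if c.is_leca]
    if not leca:
        return [], [], "no LECA clade"

    # near-universality is a property of the whole family
    by_domain = tax.species_by_domain(ml_tree.leaves)
    universal = near_universal_filter(by_domain, tax,
                                      config.near_universal_fraction)

    rows, ambiguous = [], []
    for index, clade in enumerate(leca, start=1):
        if len(clade.leaves) > config.k_representatives:
            subtree = work.restrict_to(clade.leaves)
            reps = sample_representatives(subtree, config.k_representatives)
        else:
            reps = clade.leaves
        kept_leaves = work.leaves - (clade.leaves - reps)
        ml_r = work.restrict_to(kept_leaves)
        reps_r = None
        if replicates is not None:
            reps_r = [rep.restrict_to(kept_leaves & rep.leaves)
                      for rep in replicates]
            support = monophyly_support(reps_r, reps)
            if support <= config.retention_threshold:
                ambiguous.append((family_id, index, support))
                continue
        else:
            logger.warning("%s: no bootstrap replicates; ML-only row",
                           family_id)
            support = float("nan")

        ml_label = classify_configuration(ml_r, reps, tax, config.thresholds)
        if reps_r is not None:
            profile = bootstrap_configuration_profile(
                reps_r, reps, tax, config.thresholds)
            modal = profile.modal
            freqs = _serialize_freqs(dict(profile.frequencies))
            fractions = _serialize_freqs(
                {(GROUP_RELATED, g): f
                 for g, f in profile.group_fractions.items()})
            try:
                sup = clade_support(f"{family_id}.{index}", ml_r, reps_r, reps)
                nbs_val, sgs_pct = sup.nbs, sup.sgs_percent
                g_ml = leafset_str(sup.g_ml)
            except NotAClanError:
                nbs_val, sgs_pct, g_ml = float("nan"), float("nan"), ""
            arch = frozenset(x for x in ml_r.leaves
                             if tax.domain(x) == "Archaea")
            bact = frozenset(x for x in ml_r.leaves
                             if tax.domain(x) == "Bacteria")
            arch_sup = (monophyly_support(reps_r, arch) if arch
                        else float("nan"))
            bact_sup = (monophyly_support(reps_r, bact) if bact
                        else float("nan"))
        else:
            modal = ml_label
            freqs, fractions, g_ml = "", "", ""
            nbs_val = sgs_pct = arch_sup = bact_sup = float("nan")
            try:
                g_ml = leafset_str(ml_r.sister_group(reps).leaves)
            except NotAClanError:
                pass

        rows.append(CladeReportRow(
            cluster_id=family_id,
            clade_index=index,
            n_leaves=len(clade.leaves),
            rules=",".join(sorted(clade.rules_satisfied)),
            representatives=leafset_str(reps),
            ml_config=ml_label.kind,
            ml_group=ml_label.group or "",
            modal_config=modal.kind,
            modal_group=modal.group or "",
            frequencies=freqs,
            group_fractions=fractions,
            nbs=nbs_val,
            sgs_percent=sgs_pct,
            g_ml=g_ml,
            monophyly_support=support,
            near_universal=universal,
            archaea_monophyly=arch_sup,
            bacteria_monophyly=bact_sup,
            reference_flag=family_id in config.reference_families,
            intruders_removed=",".join(clade.intruders_removed),
        ))
    return rows, ambiguous, None


def run_pipeline(input_dir, taxonomy, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run detection → sampling → classification → support over a directory.

    ``taxonomy`` is a TSV path or a TaxonomyMap. Families missing a replicate
    file get an ML-only row (supports blank) with a warning; taxonomy gaps are
    a hard error.
    """
    config = config or PipelineConfig()
    tax = taxonomy if isinstance(taxonomy, TaxonomyMap) else read_taxonomy(
        taxonomy)
    families = discover_families(input_dir)
    if not families:
        logger.warning("no families found in %s", input_dir)
    rows, no_leca, ambiguous = [], [], []
    for family_id, ml_path, boot_path in families:
        ml_tree = read_newick(ml_path)
        if isinstance(ml_tree, list):
            raise PipelineError(f"{ml_path}: expected a single ML tree")
        replicates = (read_bootstrap_trees(boot_path)
                      if boot_path is not None else None)
        try:
            fam_rows, fam_ambiguous, reason = analyze_family(
                family_id, ml_tree, replicates, tax, config)
        except ConfigurationError as exc:
            logger.warning("%s: %s", family_id, exc)
            no_leca.append((family_id, str(exc)))
            continue
        if reason is not None:
            no_leca.append((family_id, reason))
        elif fam_rows:
            rows.extend(fam_rows)
            ambiguous.extend(fam_ambiguous)
        else:
            ambiguous.extend(fam_ambiguous)
    return PipelineResult(rows=rows, no_leca=no_leca, ambiguous=ambiguous,
                          n_families=len(families))


def summarize_universal(result: PipelineResult, tax: TaxonomyMap | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Domain-monophyly view over near-universal clades.

    Restricts the report to near-universal families whose clades are not
    bacteria-related (those are organellar transfers, uninformative about the
    Eukarya–Archaea relationship) and tabulates the bootstrap support for the
    monophyly of Archaea and of Bacteria, with means and 10-point histogram
    bins.
    """
    frame = result.report
    empty_stats = {"mean_archaea": float("nan"),
                   "mean_bacteria": float("nan"),
                   "histogram": pd.DataFrame()}
    if frame.empty:
        logger.info("no rows to summarize")
        return frame, empty_stats
    group_domain: dict[str, str] = {}
    if tax is not None:
        for rec in tax.records:
            group_domain.setdefault(rec.group, rec.domain)
    bacterial_group = frame["ml_group"].map(
        lambda g: group_domain.get(g) == "Bacteria" if g else False)
    bacteria_related = frame["ml_config"].eq(BACTERIAL_DOMAIN_RELATED) | (
        frame["ml_config"].eq(GROUP_RELATED) & bacterial_group)
    keep = frame[frame["near_universal"] & ~bacteria_related
                 & frame["archaea_monophyly"].notna()
                 & frame["bacteria_monophyly"].notna()]
    keep = keep[["cluster_id", "clade_index", "archaea_monophyly",
                 "bacteria_monophyly"]].reset_index(drop=True)
    if keep.empty:
        logger.info("no near-universal clades in the report")
        return keep, empty_stats
    edges = list(range(0, 101, 10))
    hist = pd.DataFrame({
        "bin": [f"{edges[i]}-{edges[i + 1]}" for i in range(len(edges) - 1)],
        "archaea": pd.cut(keep["archaea_monophyly"], edges,
                          include_lowest=True).value_counts(sort=False).values,
        "bacteria": pd.cut(keep["bacteria_monophyly"], edges,
                           include_lowest=True).value_counts(sort=False).values,
    })
    return keep, {"mean_archaea": float(keep["archaea_monophyly"].mean()),
                  "mean_bacteria": float(keep["bacteria_monophyly"].mean()),
                  "histogram": hist}


def write_report(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "clades.tsv", sep="\t", index=False)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "discarded.tsv", "w", encoding="utf-8") as handle:
        handle.write("family_id\tdetail\n")
        for fam, reason in result.no_leca:
            handle.write(f"{fam}\tno_leca: {reason}\n")
        for fam, index, support in result.ambiguous:
            handle.write(f"{fam}\tambiguous clade {index} "
                         f"(monophyly support {support:.0f}%)\n")
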