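"""miRNA-target collection and hypergeometric pathway over-representation.

Validated miRNA->mRNA target maps (TSV) and pathway gene sets (GMT) are read
into plain mappings; the union of targets of a miRNA set is tested for
over-representation in each pathway with the upper-tail hypergeometric
distribution, BH-adjusted across pathways.  The gene universe is the union of
all pathway genes, so results are reproducible from the inputs alone.
Pathways are kept when adjusted p < alpha and at least ``min_mirnas`` query
miRNAs contribute a target to the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import adjust_bh
from .matrix import ValidationError


@dataclass
class TargetMap:
    targets: dict[str, set[str]]
    provenance: str = "validated, 3'UTR"

    def __post_init__(self) -> None:
        for m, genes in self.targets.items():
            if any(not g for g in genes):
                raise ValidationError(f"empty gene symbol under {m}")


@dataclass
class PathwayDB:
    pathways: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(not v for v in self.pathways.values()):
            raise ValidationError("empty pathway gene set")
        union = set().union(*self.pathways.values()) if self.pathways else set()
        if not self.universe:
            self.universe = union
        elif not union <= self.universe:
            raise ValidationError("pathway genes outside the declared universe")


def load_target_map(path) -> TargetMap:
    """Read a two-column TSV (mirna_id, gene); duplicates are deduplicated."""
    targets: dict[str, set[str]] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["mirna_id", "gene"]:
                continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValidationError(f"{path}: malformed target-map line {lineno}")
            targets.setdefault(parts[0], set()).add(parts[1])
            n += 1
    if n == 0:
        raise ValidationError(f"{path}: empty target map")
    return TargetMap(targets)


def load_gmt(path) -> PathwayDB:
    """Read GMT lines ``name<TAB>description<TAB>gene...``."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not parts[0]:
                raise ValidationError(f"{path}: malformed GMT line {lineno}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValidationError(f"{path}: pathway without genes at line {lineno}")
            pathways[parts[0]] = genes
    if not pathways:
        raise ValidationError(f"{path}: empty GMT file")
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in db.pathways.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def write_target_map(tm: TargetMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene\n")
        for m in sorted(tm.targets):
            for g in sorted(tm.targets[m]):
                fh.write(f"{m}\t{g}\n")


def collect_targets(mirnas, tmap: TargetMap) -> tuple[set[str], dict[str, set[str]], list[str]]:
    """Union of validated targets; returns (union, per-miRNA sets, unmapped list)."""
    per: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for m in sorted(mirnas):
        if m in tmap.targets:
            per[m] = set(tmap.targets[m])
        else:
            unmapped.append(m)
    union = set().union(*per.values()) if per else set()
    return union, per, unmapped


def ora(query: set[str], db: PathwayDB,
        per_mirna: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set against each pathway.

    raw_p = P(X >= k) with universe N, pathway size K, query size n, overlap k.
    Query genes outside the universe are dropped.  Returns one row per
    pathway with contributing miRNAs/targets when a per-miRNA map is given.
    """
    if not db.universe:
        raise ValidationError("empty gene universe")
    n_total = len(db.universe)
    query_in = set(query) & db.universe
    rows = []
    for name, genes in db.pathways.items():
        overlap = query_in & genes
        k, big_k, n = len(overlap), len(genes), len(query_in)
        raw_p = float(hypergeom.sf(k - 1, n_total, big_k, n)) if k > 0 else 1.0
        contributing, contrib_targets = [], set()
        if per_mirna is not None:
            for m, tset in per_mirna.items():
                hits = tset & overlap
                if hits:
                    contributing.append(m)
                    contrib_targets |= hits
        rows.append({
            "pathway": name, "overlap": k, "pathway_size": big_k,
            "query_size": n, "universe_size": n_total,
            "raw_p": min(raw_p, 1.0),
            "n_mirnas": len(contributing),
            "mirnas": ";".join(sorted(contributing)),
            "targets": ";".join(sorted(overlap)),
        })
    res = pd.DataFrame(rows).set_index("pathway")
    res["adj_p"] = adjust_bh(res["raw_p"].to_numpy())
    return res


def filter_pathways(res: pd.DataFrame, alpha: float = 0.01,
                    min_mirnas: int = 3) -> pd.DataFrame:
    """Significant pathways: adj_p < alpha AND >= min_mirnas contributing
    miRNAs; ranked by ascending adjusted p."""
    keep = res[(res["adj_p"] < alpha) & (res["n_mirnas"] >= min_mirnas)]
    return keep.sort_values(["adj_p", "raw_p"]).copy()
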