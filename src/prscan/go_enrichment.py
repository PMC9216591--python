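"""GO-term over-representation with a resampling-based FDR.

Ontology terms come from an OBO file (parsed with ``obonet``); gene-to-term
annotations from a GAF 2.x file.  Annotations carrying evidence codes that
would leak the network itself back into the test (ND, IGI, HGI by default)
are excluded, and annotations are restricted to the background population of
network genes.

Per term, over-representation in a study set is scored by the one-sided
Fisher exact test (hypergeometric tail).  Multiple testing is controlled by
a resampling-based FDR: the same battery of tests is re-run on random study
sets of identical size, and the FDR of a term is the empirical probability
(r+1)/(n+1) that a random set achieves a p-value at least as small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: evidence codes excluded by default (derived from genetic-interaction data)
DEFAULT_EXCLUDED_CODES = frozenset({"ND", "IGI", "HGI"})


@dataclass
class AnnotationSet:
    """Ontology DAG plus filtered gene -> term annotations over a population."""

    ontology: "object"  # networkx DiGraph from obonet (child -> parent edges)
    gene_terms: dict  # gene -> set of term ids
    population: set
    term_names: dict = field(default_factory=dict)

    def term_genes(self) -> dict:
        out: dict = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out


@dataclass
class EnrichmentResult:
    term: str
    name: str
    study_count: int
    study_n: int
    pop_count: int
    pop_n: int
    p_fisher: float
    fdr: float
    significant: bool


def read_gaf(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Parse a GAF 2.x file into (gene_id, symbol, term, evidence) tuples.

    Comment lines start with ``!``; fields are tab-separated with the DB
    object id in column 2, symbol in column 3, qualifier in column 4, GO id
    in column 5 and evidence code in column 7.  Rows whose qualifier negates
    the annotation (``NOT|...``) are dropped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise ValueError(f"malformed GAF row: {line[:80]!r}")
            qualifier = f[3]
            if "NOT" in qualifier.split("|"):
                continue
            rows.append((f[1], f[2], f[4], f[6]))
    return rows


def load_annotations(
    obo_path: str | Path | None,
    gaf_path: str | Path,
    population,
    excluded_codes=DEFAULT_EXCLUDED_CODES,
    id_field: str = "symbol",
    propagate: bool = False,
) -> AnnotationSet:
    """Load ontology + annotations restricted to a gene population.

    Parameters
    ----------
    obo_path
        OBO ontology file; ``None`` skips the DAG (term names then unavailable
        and ``propagate`` must be False).
    gaf_path
        GAF 2.x annotation file.
    population
        Background gene set (all network nodes).
    excluded_codes
        Evidence codes to drop (default: ND, IGI, HGI, which derive from the
        genetic-interaction data the networks are built on).
    id_field
        Which GAF column identifies genes: ``"symbol"`` (column 3) or
        ``"id"`` (column 2).
    propagate
        Climb is_a/part_of edges so each gene is annotated to every ancestor
        of its direct terms.  Off by default.
    """
    if id_field not in ("symbol", "id"):
        raise ValueError(f"unknown id_field {id_field!r}")
    population = set(population)
    ontology = None
    term_names: dict = {}
    obsolete: set = set()
    if obo_path is not None:
        import obonet

        ontology = obonet.read_obo(obo_path)
        term_names = {
            t: d.get("name", t) for t, d in ontology.nodes(data=True)
        }
    elif propagate:
        raise ValueError("propagation requires an ontology")

    excluded = frozenset(excluded_codes)
    gene_terms: dict = {}
    n_dropped_code = n_dropped_pop = n_obsolete = 0
    for gid, symbol, term, evidence in read_gaf(gaf_path):
        gene = symbol if id_field == "symbol" else gid
        if evidence in excluded:
            n_dropped_code += 1
            continue
        if gene not in population:
            n_dropped_pop += 1
            continue
        if ontology is not None and term not in ontology:
            # obonet drops obsolete terms from the graph
            n_obsolete += 1
            continue
        gene_terms.setdefault(gene, set()).add(term)
    if not gene_terms:
        raise ValueError("no annotations intersect the population")
    logger.info(
        "annotations: kept %d genes; dropped %d by evidence code, "
        "%d outside population, %d obsolete terms",
        len(gene_terms), n_dropped_code, n_dropped_pop, n_obsolete,
    )
    if propagate:
        ancestors_cache: dict = {}

        def ancestors(t):
            if t not in ancestors_cache:
                seen = set()
                stack = [t]
                while stack:
                    cur = stack.pop()
                    for _, parent, key in ontology.out_edges(cur, keys=True):
                        if key in ("is_a", "part_of") and parent not in seen:
                            seen.add(parent)
                            stack.append(parent)
                ancestors_cache[t] = seen
            return ancestors_cache[t]

        for gene in gene_terms:
            direct = set(gene_terms[gene])
            for t in direct:
                gene_terms[gene] |= ancestors(t)
    return AnnotationSet(
        ontology=ontology,
        gene_terms=gene_terms,
        population=population,
        term_names=term_names,
    )


def _term_pvalues(
    study: set, term_genes: dict, pop_n: int, terms: list
) -> np.ndarray:
    """One-sided Fisher (hypergeometric upper tail) p per term."""
    study_n = len(study)
    ps = np.empty(len(terms))
    for k, t in enumerate(terms):
        genes = term_genes[t]
        count = len(study & genes)
        # P[X >= count], X ~ Hypergeom(pop_n, |genes|, study_n)
        ps[k] = stats.hypergeom.sf(count - 1, pop_n, len(genes), study_n)
    return ps


def enrich(
    study,
    ann: AnnotationSet,
    n_resamples: int = 500,
    rng_seed: int = 0,
    fdr_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """Per-term over-representation of a study set with resampling FDR.

    The same ``n_resamples`` random study sets (uniform draws of identical
    size from the population) are reused across terms; the FDR of a term is
    (r+1)/(n_resamples+1) where r counts resampled sets whose p-value for
    that term is <= the observed one.
    """
    study = set(study)
    if not study:
        raise ValueError("empty study set")
    if not study <= ann.population:
        raise ValueError("study set not contained in population")
    term_genes = ann.term_genes()
    terms = sorted(term_genes)
    pop_n = len(ann.population)
    obs_p = _term_pvalues(study, term_genes, pop_n, terms)

    rng = np.random.default_rng(rng_seed)
    pop_list = sorted(ann.population, key=str)
    null_p = np.empty((n_resamples, len(terms)))
    for s in range(n_resamples):
        rand = set(rng.choice(len(pop_list), size=len(study), replace=False))
        rand_genes = {pop_list[i] for i in rand}
        null_p[s] = _term_pvalues(rand_genes, term_genes, pop_n, terms)

    r = (null_p <= obs_p[None, :]).sum(axis=0)
    fdr = (r + 1) / (n_resamples + 1)

    results = []
    for k, t in enumerate(terms):
        genes = term_genes[t]
        results.append(
            EnrichmentResult(
                term=t,
                name=ann.term_names.get(t, t),
                study_count=len(study & genes),
                study_n=len(study),
                pop_count=len(genes),
                pop_n=pop_n,
                p_fisher=float(obs_p[k]),
                fdr=float(fdr[k]),
                significant=bool(fdr[k] < fdr_threshold),
            )
        )
    results.sort(key=lambda r: (r.p_fisher, r.term))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "name": [r.name for r in results],
            "study_count": [r.study_count for r in results],
            "study_n": [r.study_n for r in results],
            "pop_count": [r.pop_count for r in results],
            "pop_n": [r.pop_n for r in results],
            "p_fisher": [r.p_fisher for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
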