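"""In-silico panel QC: intramolecular probe–probe interaction screening.

Every unordered pair of probes on an assembled panel is checked for the
ability to form a stable duplex with each other instead of with their
targets.  The check slides one probe along the reverse complement of the
other (an exhaustive offset scan), finds the longest perfectly complementary
stretch of the best register, and evaluates that stretch with the
nearest-neighbor model.  A pair conflicts when the stretch's duplex is too
stable: dG37 at or below a threshold (default −18 kcal/mol) or duplex Tm at
or above a threshold (default 40 °C).  Conflicts are resolved iteratively by
swapping the worse-ranked member of each conflicting pair for its gene's
next-best alternative probe pair and re-screening until clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import (ContractError, NonConvergenceError, UnresolvableError)
from .io_model import PanelDefinition, PanelEntry
from .probe_design import ProbePair
from .thermo import (DEFAULT_NA_MOLAR, delta_g37, is_canonical,
                     melting_temperature, reverse_complement)

DEFAULT_DG_THRESHOLD = -18.0   # kcal/mol at 37 °C
DEFAULT_TM_THRESHOLD = 40.0    # °C
MIN_STRETCH = 8                # shortest complementary island worth scoring


@dataclass(frozen=True)
class InteractionResult:
    probe_i: str
    probe_j: str
    duplex_tm: float   # −inf when no stretch >= MIN_STRETCH exists
    delta_g: float     # 0.0 sentinel when no stretch >= MIN_STRETCH exists
    stretch_length: int
    conflict: bool


def _longest_match_stretch(a: str, b: str) -> tuple[int, str]:
    """Longest common aligned run between a and b over all offsets.

    Returns ``(run_length, run_sequence)`` where the run sequence is taken
    from ``a``.  Classic O(len(a)*len(b)) diagonal scan.
    """
    best_len = 0
    best_seq = ""
    for diag in range(-(len(b) - 1), len(a)):
        run = 0
        start = 0
        lo = max(0, diag)
        hi = min(len(a), len(b) + diag)
        for i in range(lo, hi):
            if a[i] == b[i - diag]:
                if run == 0:
                    start = i
                run += 1
                if run > best_len:
                    best_len = run
                    best_seq = a[start:start + run]
            else:
                run = 0
    return best_len, best_seq


def pairwise_interaction(a: str, b: str,
                         dg_threshold: float = DEFAULT_DG_THRESHOLD,
                         tm_threshold: float = DEFAULT_TM_THRESHOLD,
                         na_molar: float = DEFAULT_NA_MOLAR
                         ) -> InteractionResult:
    """Score the strongest possible duplex between two probe oligos.

    Complementary stretches between ``a`` and ``b`` are exactly the common
    substrings of ``a`` and reverse_complement(b); the longest one (over all
    registers) is evaluated with the nearest-neighbor model.
    """
    for seq in (a, b):
        if len(seq) < 8:
            raise ContractError(f"probe too short to screen ({len(seq)} nt)")
        if not is_canonical(seq):
            raise ContractError("non-canonical bases in probe sequence")
    n, stretch = _longest_match_stretch(a, reverse_complement(b))
    if n < MIN_STRETCH:
        return InteractionResult(probe_i=a, probe_j=b, duplex_tm=-math.inf,
                                 delta_g=0.0, stretch_length=n, conflict=False)
    tm = melting_temperature(stretch, na_molar=na_molar)
    dg = delta_g37(stretch, na_molar=na_molar)
    conflict = dg <= dg_threshold or tm >= tm_threshold
    return InteractionResult(probe_i=a, probe_j=b, duplex_tm=tm, delta_g=dg,
                             stretch_length=n, conflict=conflict)


def _entry_oligos(e: PanelEntry) -> list[str]:
    return [s for s in (e.probe_a, e.probe_b) if s]


def screen_panel(panel: PanelDefinition,
                 dg_threshold: float = DEFAULT_DG_THRESHOLD,
                 tm_threshold: float = DEFAULT_TM_THRESHOLD
                 ) -> list[tuple[int, int, InteractionResult]]:
    """Evaluate every unordered pair of panel entries.

    For each entry pair all probe-oligo combinations are scored and the most
    severe interaction (lowest dG) is kept.  Returns the conflicting pairs
    as ``(i, j, result)`` in deterministic panel-entry order.
    """
    conflicts = []
    for i in range(len(panel.entries)):
        oi = _entry_oligos(panel.entries[i])
        for j in range(i + 1, len(panel.entries)):
            oj = _entry_oligos(panel.entries[j])
            worst: InteractionResult | None = None
            for a in oi:
                for b in oj:
                    res = pairwise_interaction(a, b, dg_threshold, tm_threshold)
                    if worst is None or res.delta_g < worst.delta_g:
                        worst = res
            if worst is not None and worst.conflict:
                conflicts.append((i, j, worst))
    return conflicts


def _with_pair(entry: PanelEntry, pair: ProbePair) -> PanelEntry:
    return replace(entry, probe_a=pair.probe_a.sequence,
                   probe_b=pair.probe_b.sequence)


def resolve_conflicts(panel: PanelDefinition,
                      alternatives: dict[str, list[ProbePair]],
                      max_rounds: int = 10,
                      dg_threshold: float = DEFAULT_DG_THRESHOLD,
                      tm_threshold: float = DEFAULT_TM_THRESHOLD
                      ) -> tuple[PanelDefinition, list[str]]:
    """Iteratively swap conflicting probes for next-ranked alternatives.

    ``alternatives[gene]`` is that gene's candidate list ranked best-first
    (as produced by :func:`~panelign.probe_design.design_probe_candidates`).
    In each round the worse-ranked member of every conflicting pair is
    replaced by its gene's next alternative; the panel is re-screened until
    conflict-free.  Raises UnresolvableError when a conflict persists with
    no alternatives left, NonConvergenceError when ``max_rounds`` runs out.

    Returns the conflict-free panel and a log of replacements.
    """
    entries = list(panel.entries)
    # current candidate index per gene, recovered by sequence match
    cur_idx: dict[str, int] = {}
    for e in entries:
        cands = alternatives.get(e.mouse_gene, [])
        cur_idx[e.mouse_gene] = next(
            (k for k, c in enumerate(cands)
             if c.probe_a.sequence == e.probe_a
             and c.probe_b.sequence == e.probe_b), 0)
    log: list[str] = []
    for round_no in range(1, max_rounds + 1):
        trial = PanelDefinition(entries=entries, capacity=panel.capacity)
        conflicts = screen_panel(trial, dg_threshold, tm_threshold)
        if not conflicts:
            return trial, log

        replaced_this_round: set[str] = set()
        progress = False
        for i, j, res in conflicts:
            gi, gj = entries[i].mouse_gene, entries[j].mouse_gene
            if gi in replaced_this_round or gj in replaced_this_round:
                continue  # already swapped this round; re-screen first

            def rank(g: str) -> tuple:
                cands = alternatives.get(g, [])
                k = cur_idx.get(g, 0)
                if k < len(cands):
                    return cands[k].composite_rank_key
                return (math.inf,)

            # replace the worse-ranked member; fall back to the other one
            order = sorted([(i, gi), (j, gj)],
                           key=lambda t: (rank(t[1]), t[0]), reverse=True)
            swapped = False
            for idx, gene in order:
                cands = alternatives.get(gene, [])
                nxt = cur_idx.get(gene, 0) + 1
                if nxt < len(cands):
                    cur_idx[gene] = nxt
                    entries[idx] = _with_pair(entries[idx], cands[nxt])
                    replaced_this_round.add(gene)
                    log.append(
                        f"round {round_no}: replaced probe for {gene} "
                        f"(alternative #{nxt}) to clear conflict with "
                        f"{gj if gene == gi else gi} "
                        f"(dG={res.delta_g:.2f} kcal/mol, Tm={res.duplex_tm:.1f} C)")
                    swapped = True
                    progress = True
                    break
            if not swapped:
                raise UnresolvableError(
                    f"conflict between {gi} and {gj} "
                    f"(dG={res.delta_g:.2f} kcal/mol, Tm={res.duplex_tm:.1f} C) "
                    f"with no alternatives left for either gene")
        if not progress:
            raise UnresolvableError(
                "no replacement possible for remaining conflicts: "
                + "; ".join(f"{entries[i].mouse_gene}~{entries[j].mouse_gene}"
                            for i, j, _ in conflicts))
    raise NonConvergenceError(
        f"panel not conflict-free after {max_rounds} rounds")
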