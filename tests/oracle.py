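"""Independent brute-force alignment oracle.

Enumerates, with plain string operations and no shortcuts, every reference
window and every error pattern admitted by each hierarchy stage, applying
the documented tie-breaks (leftmost window, lexicographically smallest error
set).  Used to validate the production aligner on toy references; it shares
no code with it.
"""

import itertools

from tdrkit.align import ErrorType, Placement


def oracle_find(read_seq: str, family, stage: ErrorType) -> list[Placement]:
    if family.kind != stage.target_kind:
        return []
    ref = family.sequence
    L = len(read_seq)
    if stage.n_mismatches == 0 and stage.n_deletions == 0:
        for s in range(len(ref) - L + 1):
            if ref[s : s + L] == read_seq:
                return [Placement(family.name, s + 1, L)]
        return []
    if stage.n_mismatches:
        k = stage.n_mismatches
        for s in range(len(ref) - L + 1):
            window = ref[s : s + L]
            mism = [i for i in range(L) if window[i] != read_seq[i]]
            if len(mism) == k:
                return [Placement(family.name, s + 1, L,
                                  mismatch_positions=tuple(s + i + 1 for i in mism))]
        return []
    k = stage.n_deletions
    width = L + k
    for s in range(len(ref) - width + 1):
        window = ref[s : s + width]
        combos = ([tuple(range(g, g + k)) for g in range(width - k + 1)]
                  if stage.contiguous else
                  list(itertools.combinations(range(width), k)))
        for combo in combos:
            kept = "".join(window[i] for i in range(width) if i not in combo)
            if kept == read_seq:
                return [Placement(family.name, s + 1, width,
                                  deletion_positions=tuple(s + i + 1 for i in combo))]
    return []


def oracle_assign(read_seq: str, mature_lib, pre_lib, stage_order):
    """(stage, placements) for the first stage with any placement, or
    (None, []) if the read is unmapped."""
    libs = {"mature": mature_lib, "pre": pre_lib}
    for stage in stage_order:
        placements = []
        for family in libs[stage.target_kind]:
            placements.extend(oracle_find(read_seq, family, stage))
        if placements:
            return stage, placements
    return None, []
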