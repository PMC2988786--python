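import itertools
import re

import numpy as np
import pytest

from zfclass import (
    ProteinRecord,
    ScanParams,
    ZFDomainHit,
    assemble_architecture,
    find_c2h2_hits,
    trim_nterm_region,
    trim_zf_region,
    zf1_spacing_diagnostic,
)
from zfclass.synthetic_data import GeneratorParams, make_protein

DEFAULTS = ScanParams()

# Independent oracle: one compiled regex (with capture-in-lookahead so
# overlapping instances are found) per realized (cc, ch, hh) gap triple.
_ORACLE_PATTERNS = [
    (
        re.compile(f"(?=(C.{{{a}}}C.{{{b}}}H.{{{c}}}H))"),
        a,
        b,
        c,
    )
    for a in range(DEFAULTS.cc_min, DEFAULTS.cc_max + 1)
    for b in range(DEFAULTS.ch_min, DEFAULTS.ch_max + 1)
    for c in range(DEFAULTS.hh_min, DEFAULTS.hh_max + 1)
]


def regex_oracle_hits(seq: str) -> set[tuple[int, int, int, int]]:
    quads = set()
    for pat, a, b, c in _ORACLE_PATTERNS:
        for m in pat.finditer(seq):
            c1 = m.start()
            c2 = c1 + a + 1
            h1 = c2 + b + 1
            h2 = h1 + c + 1
            quads.add((c1, c2, h1, h2))
    return quads


def exhaustive_best_chain(hits, k, max_linker):
    """Oracle for assembly: brute force over all k-subsets of candidates."""
    best_key, best = None, None
    for combo in itertools.combinations(sorted(hits, key=lambda h: h.start), k):
        ok = all(
            0 <= b.start - a.end <= max_linker
            for a, b in itertools.pairwise(combo)
        )
        if not ok:
            continue
        key = (
            combo[-1].his2 - combo[0].cys1 + 1,
            combo[0].cys1,
            tuple(p for h in combo for p in (h.cys1, h.cys2, h.his1, h.his2)),
        )
        if best_key is None or key < best_key:
            best_key, best = key, combo
    return best


class TestFindHits:
    def test_constructed_single_hit(self):
        rec = ProteinRecord("t", "AACAACAAAAAAAAAAAAHAAAHAA")
        hits = find_c2h2_hits(rec)
        assert len(hits) == 1
        (h,) = hits
        assert (h.spacer_cc, h.spacer_hh) == (2, 3)
        assert rec.sequence[h.cys1] == rec.sequence[h.cys2] == "C"
        assert rec.sequence[h.his1] == rec.sequence[h.his2] == "H"

    def test_no_hits_in_polyalanine(self):
        assert find_c2h2_hits(ProteinRecord("t", "A" * 80)) == []

    def test_expanded_zf1_needs_wide_cc_bound(self):
        seq = "C" + "A" * 12 + "C" + "A" * 12 + "H" + "A" * 4 + "H"
        rec = ProteinRecord("t", seq)
        assert len(find_c2h2_hits(rec, ScanParams())) == 1
        narrow = ScanParams(cc_max=11)
        assert find_c2h2_hits(rec, narrow) == []

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        """The scanner must report exactly the exhaustive pattern instances."""
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        # boost C/H so hits actually occur
        probs = np.ones(20)
        probs[alphabet.index("C")] = 4
        probs[alphabet.index("H")] = 4
        probs = probs / probs.sum()
        checked_nonempty = 0
        for _ in range(500):
            n = int(rng.integers(30, 301))
            seq = "".join(rng.choice(alphabet, size=n, p=probs))
            got = {
                (h.cys1, h.cys2, h.his1, h.his2)
                for h in find_c2h2_hits(ProteinRecord("r", seq))
            }
            expected = regex_oracle_hits(seq)
            assert got == expected
            checked_nonempty += bool(expected)
        assert checked_nonempty > 100  # the comparison exercised real hits


class TestAssembleArchitecture:
    def _tandem(self, n, spacer=3, linker=7):
        finger = "C" + "A" * spacer + "C" + "A" * 12 + "H" + "A" * 4 + "H"
        return ProteinRecord("t", ("A" * 10) + (finger + "A" * linker) * n)

    def test_five_even_fingers(self):
        rec = self._tandem(5)
        arch = assemble_architecture(find_c2h2_hits(rec))
        assert arch is not None and len(arch.hits) == 5
        assert len(set(arch.linkers)) == 1

    def test_four_fingers_is_none_by_default(self):
        rec = self._tandem(4)
        assert assemble_architecture(find_c2h2_hits(rec)) is None

    def test_partial_mode_returns_flagged_four_chain(self):
        rec = self._tandem(4)
        arch = assemble_architecture(
            find_c2h2_hits(rec), ScanParams(allow_partial=True)
        )
        assert arch is not None and len(arch.hits) == 4 and arch.partial

    def test_linker_cap_respected(self):
        rec = self._tandem(5, linker=20)
        assert assemble_architecture(find_c2h2_hits(rec)) is None
        arch = assemble_architecture(find_c2h2_hits(rec), ScanParams(max_linker=25))
        assert arch is not None

    def test_chain_equals_exhaustive_subset_oracle(self, rng):
        """Random candidate sets (<=12 hits): DFS chain == brute-force best."""
        for _ in range(300):
            n_hits = int(rng.integers(5, 13))
            hits = []
            pos = 0
            for _ in range(n_hits):
                c1 = pos + int(rng.integers(0, 12))
                c2 = c1 + 1 + int(rng.integers(2, 26))
                h1 = c2 + 1 + int(rng.integers(9, 17))
                h2 = h1 + 1 + int(rng.integers(3, 7))
                hits.append(ZFDomainHit(c1, c2, h1, h2))
                # sometimes overlap the next candidate with this one
                pos = c1 + 2 if rng.random() < 0.4 else h2 + 1 + int(rng.integers(0, 18))
            arch = assemble_architecture(hits, ScanParams())
            oracle = exhaustive_best_chain(hits, 5, DEFAULTS.max_linker)
            if oracle is None:
                assert arch is None
            else:
                assert arch is not None
                assert [
                    (h.cys1, h.cys2, h.his1, h.his2) for h in arch.hits
                ] == [(h.cys1, h.cys2, h.his1, h.his2) for h in oracle]

    def test_generator_proteins_recover_planted_architecture(self, rng):
        """mu=0 synthetic proteins: exactly the planted 5-ZF chain, exact spacing."""
        params = GeneratorParams(mu=0.0)
        for label in ("zic", "gli", "glis", "nkl"):
            for _ in range(10):
                rec, truth = make_protein(label, params, rng)
                arch = assemble_architecture(find_c2h2_hits(rec))
                assert arch is not None and not arch.partial
                assert [
                    (h.cys1, h.cys2, h.his1, h.his2) for h in arch.hits
                ] == [(h.cys1, h.cys2, h.his1, h.his2) for h in truth.zf_hits]
                assert arch.zf1_spacing == truth.zf1_spacing


class TestDiagnosticAndTrimming:
    def _arch(self, seq):
        return assemble_architecture(find_c2h2_hits(ProteinRecord("t", seq)))

    def test_spacing_diagnostic_thresholds(self):
        finger = "C" + "A" * 3 + "C" + "A" * 12 + "H" + "A" * 4 + "H"
        zic_zf1 = "C" + "A" * 12 + "C" + "A" * 12 + "H" + "A" * 4 + "H"
        gli = ProteinRecord("g", (finger + "A" * 7) * 5)
        zic = ProteinRecord("z", zic_zf1 + "A" * 7 + (finger + "A" * 7) * 4)
        garch = assemble_architecture(find_c2h2_hits(gli))
        zarch = assemble_architecture(find_c2h2_hits(zic))
        assert not zf1_spacing_diagnostic(garch, 8)
        assert zf1_spacing_diagnostic(zarch, 8)

    def test_diagnostic_separates_generator_labels(self, rng):
        params = GeneratorParams(mu=0.0)
        for label in ("zic", "gli", "glis", "nkl"):
            for _ in range(15):
                rec, _ = make_protein(label, params, rng)
                arch = assemble_architecture(find_c2h2_hits(rec))
                assert zf1_spacing_diagnostic(arch, 8) == (label == "zic")

    def test_trim_zf_region_endpoints_and_idempotence(self, rng):
        rec, truth = make_protein("zic", GeneratorParams(mu=0.0), rng)
        arch = assemble_architecture(find_c2h2_hits(rec))
        trimmed = trim_zf_region(rec, arch)
        assert trimmed.startswith("C") and trimmed.endswith("H")
        assert len(trimmed) == arch.hits[-1].his2 - arch.hits[0].cys1 + 1
        rec2 = ProteinRecord("t2", trimmed)
        arch2 = assemble_architecture(find_c2h2_hits(rec2))
        assert trim_zf_region(rec2, arch2) == trimmed

    def test_trim_nterm_prefix_rule(self):
        # Cys1 at index 4 -> prefix length 7 (two residues after Cys, inclusive)
        seq = "MNPQ" + "C" + "A" * 3 + "C" + "A" * 12 + "H" + "A" * 4 + "H"
        seq = seq + ("A" * 7 + "C" + "A" * 3 + "C" + "A" * 12 + "H" + "A" * 4 + "H") * 4
        rec = ProteinRecord("t", seq)
        arch = assemble_architecture(find_c2h2_hits(rec))
        assert arch.hits[0].cys1 == 4
        prefix = trim_nterm_region(rec, arch)
        assert prefix == seq[:7]
        assert prefix + rec.sequence[len(prefix):] == rec.sequence

    def test_trim_nterm_degenerate_cys_at_start(self):
        seq = "C" + "A" * 3 + "C" + "A" * 12 + "H" + "A" * 4 + "H"
        rec = ProteinRecord("t", (seq + "A" * 7) * 5)
        arch = assemble_architecture(find_c2h2_hits(rec))
        assert trim_nterm_region(rec, arch) == rec.sequence[:3]
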