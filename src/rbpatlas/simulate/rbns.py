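"""RBNS pool simulator with an analytically tractable selection model.

Random oligos of fixed length are drawn uniformly; the pulldown library is
the input distribution tilted by s**m, where m is the number of
(overlapping) occurrences of the planted consensus in a read and s >= 1 is
the per-occurrence selection factor.  The simulator draws i.i.d. reads from
the tilted distribution exactly: the occurrence-count distribution is
computed by dynamic programming over the motif's KMP automaton, the count
is drawn from its tilted version, and a read is then drawn uniformly among
reads with exactly that count.

Because the model is an exponential tilt, the expected R value of any
k-mer (pulldown frequency / input frequency) has a closed form, computed
here by a product-automaton DP and used as the analytic reference for
recovery checks.
"""

from __future__ import annotations

import numpy as np

from ..kmers import ReadPool, encode, kmer_to_index, window_codes


# --- KMP automaton utilities ---------------------------------------------

def _failure(pattern: np.ndarray) -> np.ndarray:
    k = len(pattern)
    fail = np.zeros(k + 1, dtype=np.int64)
    for i in range(1, k):
        j = fail[i]
        while j > 0 and pattern[i] != pattern[j]:
            j = fail[j]
        fail[i + 1] = j + 1 if pattern[i] == pattern[j] else 0
    return fail


def _automaton(pattern: np.ndarray) -> np.ndarray:
    """Transition table (k+1, 4); entering state k marks an occurrence."""
    k = len(pattern)
    fail = _failure(pattern)
    trans = np.zeros((k + 1, 4), dtype=np.int64)
    for st in range(k + 1):
        for c in range(4):
            if st < k and pattern[st] == c:
                trans[st, c] = st + 1
            else:
                trans[st, c] = trans[fail[st], c] if st > 0 else 0
    return trans


def _min_period(pattern: np.ndarray) -> int:
    k = len(pattern)
    for p in range(1, k):
        if np.array_equal(pattern[p:], pattern[: k - p]):
            return p
    return k


# --- exact occurrence-count distributions --------------------------------

def motif_count_distribution(motif: str, read_len: int) -> np.ndarray:
    """P(m occurrences of motif in a uniform random read), m = 0..sites."""
    pat = encode(motif)
    k = len(pat)
    if k > read_len:
        raise ValueError("motif longer than read")
    sites = read_len - k + 1
    trans = _automaton(pat)
    dp = np.zeros((k + 1, sites + 1))
    dp[0, 0] = 1.0
    for _ in range(read_len):
        nxt = np.zeros_like(dp)
        for st in range(k + 1):
            row = dp[st]
            if not row.any():
                continue
            for c in range(4):
                t = trans[st, c]
                if t == k:
                    nxt[t, 1:] += 0.25 * row[:-1]
                else:
                    nxt[t] += 0.25 * row
        dp = nxt
    return dp.sum(axis=0)


def tilted_count_distribution(motif: str, s: float, read_len: int) -> np.ndarray:
    p0 = motif_count_distribution(motif, read_len)
    w = p0 * s ** np.arange(len(p0))
    return w / w.sum()


def expected_r_value(motif: str, s: float, kmer: str, read_len: int) -> float:
    """Exact model R value of ``kmer`` under selection (motif, s).

    R = E_tilt[c_w] / E_0[c_w] with c_w the per-read overlapping count of
    the k-mer w, computed as E_0[c_w s^m] / (E_0[s^m] E_0[c_w]) by DP over
    the product of the motif and k-mer automata.
    """
    pat = encode(motif)
    wpat = encode(kmer)
    if len(pat) > read_len or len(wpat) > read_len:
        raise ValueError("pattern longer than read")
    ta, tb = _automaton(pat), _automaton(wpat)
    ka, kb = len(pat), len(wpat)
    # z[a, b] = E[ s^m ; states ], acc[a, b] = E[ s^m * c_w ; states ]
    z = np.zeros((ka + 1, kb + 1))
    acc = np.zeros_like(z)
    z[0, 0] = 1.0
    for _ in range(read_len):
        z2 = np.zeros_like(z)
        a2 = np.zeros_like(z)
        for a in range(ka + 1):
            for b in range(kb + 1):
                if z[a, b] == 0 and acc[a, b] == 0:
                    continue
                for c in range(4):
                    na, nb = ta[a, c], tb[b, c]
                    wgt = 0.25 * (s if na == ka else 1.0)
                    z2[na, nb] += wgt * z[a, b]
                    a2[na, nb] += wgt * (acc[a, b] + (z[a, b] if nb == kb else 0.0))
        z, acc = z2, a2
    e_sm = z.sum()
    e_sm_cw = acc.sum()
    sites_w = read_len - kb + 1
    e_cw = sites_w / 4.0**kb
    return (e_sm_cw / e_sm) / e_cw


# --- exact conditional read sampling -------------------------------------

def _coverage_lengths(pos: np.ndarray, k: int) -> np.ndarray:
    """Union length of [p, p+k) per row for sorted position matrices."""
    if pos.shape[1] == 1:
        return np.full(pos.shape[0], k)
    diffs = np.minimum(np.diff(pos, axis=1), k)
    return k + diffs.sum(axis=1)


def _sample_exact_count(
    pat: np.ndarray, m: int, n: int, read_len: int, rng
) -> np.ndarray:
    """n uniform random reads containing exactly m motif occurrences."""
    k = len(pat)
    sites = read_len - k + 1
    code = int(kmer_to_index("".join("ACGU"[c] for c in pat)))
    out = []
    got = 0
    cov_min = k + (m - 1) * _min_period(pat) if m >= 1 else 0
    while got < n:
        batch = max(256, int((n - got) * 1.3) + 16)
        reads = rng.integers(0, 4, size=(batch, read_len), dtype=np.int8)
        if m == 0:
            codes = window_codes(reads, k)
            keep = ~(codes == code).any(axis=1)
        else:
            ranks = rng.random((batch, sites))
            pos = np.sort(np.argsort(ranks, axis=1)[:, :m], axis=1)
            for j in range(m):
                for t in range(k):
                    reads[np.arange(batch), pos[:, j] + t] = pat[t]
            codes = window_codes(reads, k)
            occ = codes == code
            planted = np.zeros((batch, sites), dtype=bool)
            planted[np.arange(batch)[:, None], pos] = True
            exact = (occ == planted).all(axis=1)
            # importance correction: overlapping plants cover fewer bases and
            # would otherwise be over-represented among exact-count reads
            cov = _coverage_lengths(pos, k)
            accept = 4.0 ** (cov_min - cov)
            keep = exact & (rng.random(batch) < accept)
        kept = reads[keep]
        out.append(kept[: n - got])
        got += min(len(kept), n - got)
    return np.vstack(out) if out else np.empty((0, read_len), dtype=np.int8)


def simulate_rbns(
    motif: str,
    s: float,
    n_reads: int,
    read_len: int = 20,
    seed: int = 0,
) -> tuple[ReadPool, ReadPool]:
    """Simulate (pulldown, input) RBNS pools of ``n_reads`` each."""
    if s < 1:
        raise ValueError("selection factor s must be >= 1")
    if len(motif) > read_len:
        raise ValueError("motif longer than read length")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    inp = rng.integers(0, 4, size=(n_reads, read_len), dtype=np.int8)
    pat = encode(motif)
    if s == 1.0:
        pull = rng.integers(0, 4, size=(n_reads, read_len), dtype=np.int8)
    else:
        ptilt = tilted_count_distribution(motif, s, read_len)
        counts = rng.multinomial(n_reads, ptilt)
        parts = [
            _sample_exact_count(pat, m, int(cnt), read_len, rng)
            for m, cnt in enumerate(counts)
            if cnt > 0
        ]
        pull = np.vstack(parts) if parts else np.empty((0, read_len), dtype=np.int8)
        pull = pull[rng.permutation(len(pull))]
    return ReadPool(pull), ReadPool(inp)
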