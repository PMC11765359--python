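# psrecon

Reconstruction of multisets of constant-weight binary strings from the
compositions of their prefixes and suffixes.

## The problem

In polymer- and DNA-based archival storage, a codeword is a synthesized
molecule read out by mass-spectrometry-style fragmentation: what the readout
reports for a fragment is not its sequence but its *composition* — how many
0-monomers and 1-monomers it contains.  When the observable fragments are
the prefixes and suffixes of every length, a multiset U of h binary strings
of common length n is seen only through

```
M(U) = ⋃_{t∈U} { (j − wt(t[j]), wt(t[j])), (j − wt(t[−j]), wt(t[−j])) : 1 ≤ j ≤ n }
```

the multiset of 2nh affix compositions.  A string and its reversal produce
the same compositions, so reconstruction is only ever possible up to
reversal of individual strings.  `psrecon` answers, for strings of constant
weight w̄ (all codewords carry the same number of ones):

* **one solution** — a greedy O(nh) solver returning a multiset compatible
  with M;
* **all solutions** — a two-stage enumerator (scan + assembly) returning
  every compatible multiset up to reversal;
* **uniqueness** — a necessary-and-sufficient test deciding whether M
  determines its multiset uniquely up to reversal.

The machinery underneath is the *cumulative weight function* (CWF): a grid
f(l, m) on {0..n} × [2h] where the odd label 2j−1 tracks the running prefix
weight of string j and the even label 2j its running suffix weight, so that
f(l, 2j−1) + f(n−l, 2j) = w̄.  M fixes how many component functions pass
through each grid point (l, w) — the multiplicity a_{l,w} — and splitting
each count by whether the weight persists or drops at length l−1 (the b/c
flow grids) constrains the component functions' shapes.  Uniqueness is a
statement about the discrepancy between pairs of component functions: M is
uniquely reconstructible iff every partner pair (f_m, f_m*) differs on at
most two maximal intervals and every non-partner pair on at most one.

## A worked example

```python
>>> import psrecon as pr
>>> U = pr.StringMultiset.from_strings(["110101", "110101", "101110"])
>>> M = pr.composition_multiset(U)
>>> int(M.a[3, 2])           # the composition (1 zero, 2 ones) occurs 6 times
6
>>> pr.is_unique(M).unique   # two maximal intervals between f2 and f6
False
>>> for cls in pr.reconstruct_all(M):
...     print(cls)
('011011', '101011', '101101')
('011101', '101011', '101011')
('011101', '101101', '110011')
```

Three reversal-equivalence classes are compatible with M(U) — the middle
one is U itself (each member replaced by the lexicographic minimum of
itself and its reversal).  A uniquely reconstructible instance:

```python
>>> V = pr.StringMultiset.from_strings(["1000111", "1110001", "1100011", "1010011"])
>>> MV = pr.composition_multiset(V)
>>> pr.is_unique(MV).unique
True
>>> pr.reconstruct_all(MV)
[('1000111', '1000111', '1010011', '1100011')]
```

The same pipeline from the shell:

```sh
psrecon compose --strings u.txt --out m.tsv
psrecon reconstruct --compositions m.tsv --mode all   # three JSONL classes
psrecon unique --compositions m.tsv                   # exit 1, witness pair [2,6]
psrecon simulate --n 6 --h 3 --weight 4 --seed 1 --out sim.txt
```

`unique` exits 0/1 for unique/ambiguous, 2 on invalid composition tables,
64 on usage errors.

## Layout

| module | contents |
| --- | --- |
| `psrecon.strings` | affix compositions, the a/b/c/s grids, validation, reversal canonicalization |
| `psrecon.cwf` | CWFs, maximal intervals, the solution-preserving swap, medians, branching/merging points |
| `psrecon.greedy` | the O(nh) single-solution solver |
| `psrecon.uniqueness` | the interval-count uniqueness test |
| `psrecon.enumerator` | scan and assembly stages of the complete enumeration |
| `psrecon.oracle` | brute-force ground truth and seeded fixture generation |
| `psrecon.io`, `psrecon.cli` | file formats and the `psrecon` command |

See `docs/methods.md` for the model, the algorithms, and the design
decisions in detail.
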