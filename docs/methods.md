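# Methods

## Model and observables

An instance is a multiset H of h binary strings, all of length n and weight
w̄ (constant-weight codewords are the natural regime for polymer storage
channels, where synthesis fixes the monomer budget per molecule).  The
observable is the prefix–suffix composition multiset M = M(H): for every
string and every length j ∈ [n], the pair (zeros, ones) of the length-j
prefix and of the length-j suffix — 2nh compositions counted with
multiplicity.  Reversing any member of H leaves M unchanged, so all
questions are posed up to *reversal equivalence*: two multisets are
equivalent when, member by member, the summed multiplicities of each string
and its reversal agree.  Operationally we canonicalize by replacing every
member with the lexicographic minimum of itself and its reversal and
sorting; two multisets are equivalent iff their canonical forms are equal
(for palindromes the two readings of the definition coincide, which is why
the canonical form is a sound operational relation).

## Grids

M is stored densely as a_{l,w} = multiplicity of the composition
(l−w, w), an (n+1)×(n+1) integer grid, with the convention a_{0,0} = 2h.
Valid grids satisfy: row sums Σ_w a_{l,w} = 2h for every l ∈ [n]; no mass
above the diagonal (w > l); the constant-weight point symmetry
a_{l,w} = a_{n−l, w̄−w}; and w̄ is read off row n as the unique w with
a_{n,w} = 2h.  Splitting each cell by the behavior one step left gives the
flow grids

    b_{l,w} = # affixes of length l, weight w whose weight persists at l−1
    c_{l,w} = # affixes of length l, weight w whose weight drops at l−1

computed from suffix sums s_{l,w} = Σ_{v≥w} a_{l,v} as
b_{l,w} = s_{l−1,w} − s_{l,w+1} and c_{l,w} = s_{l,w} − s_{l−1,w}.
Negative values prove that no string multiset produces the grid; the
validator reports every violated invariant with its (l, w) witness, and all
reconstruction entry points validate eagerly.

## Cumulative weight functions

A CWF f(l, m) on {0..n} × [2h] has f(0, ·) = 0, unit steps in l, and the
rotational pairing f(l, 2j−1) + f(n−l, 2j) = w̄: odd labels track prefix
weights, even labels suffix weights, and labels 2j−1, 2j (partners, written
m and m*) describe the same string read from its two ends.  f *solves* M
when it passes each grid point (l, w) exactly a_{l,w} times.  Strings are
recovered from a CWF as first differences of the odd columns.

The discrepancy D(m1, m2) is the set of positions where two component
functions differ; its maximal runs are the *maximal intervals*.  Swapping
two component functions on a maximal interval (and their partners on the
mirrored interval; once on the self-mirrored union when m2 = m1*) yields
another valid CWF solving the same M — the move that generates ambiguity.

## Uniqueness test

M determines its multiset uniquely up to reversal iff any solution CWF has
at most **two** maximal intervals between every partner pair and at most
**one** between every non-partner pair.  Three partner intervals or two
non-partner intervals admit a swap whose output is not a reversal of the
input; conversely the bound forces all solutions to share the same
component-function multiset.  The checker enumerates unordered label pairs
once (the discrepancy is symmetric, the diagonal vacuous) and reports *all*
violating pairs with their intervals, which the tests use as diagnostics.
The verdict is computed on the greedy solver's solution; it is independent
of which solution is used, and the suite checks this invariance against
the CWF induced by the generating multiset.

## Greedy single solution

Row l of a valid grid partitions the 2h affixes of length l by weight, and
the suffix sums are strictly partitioning: for every k ∈ [h] there is a
unique w with s_{l,w+1} < k ≤ s_{l,w}.  Assigning f(l, 2k−1) = w hands the
larger weights to the smaller string indices — the greedy choice, located
by walking w downward along the s-row so the whole construction is O(nh) —
and the even labels are filled purely by the mirror rule
f(l, 2k) = w̄ − f(n−l, 2k−1), never independently.  The result is asserted
to be a solution post hoc, which guards the assignment rule itself.

## Complete enumeration

Constant weight makes f_m* the 180° rotation of f_m about (n/2, w̄/2), so a
solution is determined by (i) the component behaviors on {0..⌊n/2⌋} and
(ii) a pairing of the resulting "half strings" whose median weights
med(f_m) = (f(⌊n/2⌋,m) + f(⌈n/2⌉,m))/2 sum to w̄.  Medians are carried
doubled (integers throughout; odd doubled medians are the half-integer
medians of odd n).

**Scan stage.**  The midpoint occupancies seed a partition of the 2h labels
by doubled median: row a_{n/2,·} for even n; the b/c columns at ⌈n/2⌉ for
odd n (weight kept across the midpoint ⇒ integer median, dropped ⇒
half-integer).  Sweeping l = ⌊n/2⌋ … 1 and w = w̄ … 0, each cell (l, w)
holds label groups whose histories over [l, ⌈n/2⌉] are pairwise distinct;
exactly c_{l,w} of their members must drop weight, so each admissible split
is a solution of the bounded system Σ x_i = c_{l,w}, 0 ≤ x_i ≤ |J_i|,
and the breadth-first search branches over all of them.  Groups are
label-oblivious — only (median, history, size) matter — which collapses all
relabelings of the same half-string multiset.  Each completed sweep is a
*bookkeeping leaf*: the distinct half strings with multiplicities.  Leaves
are provably pairwise distinct (the history keys never merge, so a leaf
determines every split choice); an assertion enforces this.

**Assembly stage.**  Within a leaf, groups are collected per doubled median
w into ordered lists R_w.  For each median pair (w, w̄−w) with w < w̄/2 the
pairings are the nonnegative integer matrices with row sums |R_{w,i}| and
column sums |R_{w̄−w,j}| (a transportation system); the self-paired median
w̄/2 requires symmetric matrices with even diagonal (labels inside one
group pair up two at a time; which two is immaterial because they share one
half string, so the first-fit matching is used).  Every element of the
Cartesian product over medians is one global pairing; each pair stitches
into one full string — prefix half on the left, the partner's half rotated
onto [⌈n/2⌉, n] — and the assembled CWF is asserted to solve M.  Distinct
leaves and distinct matrices yield distinct multisets up to reversal; the
output is deduplicated defensively with an assertion that the dedup never
fires.

Both stages and the bounded/transportation enumerations run in fixed
lexicographic orders, so outputs are reproducible byte for byte.  Two
orderings the method itself does not fix were chosen once: parts within a
scan cell are ordered by (size descending, history), and groups within R_w
by (size ascending, half graph).  Worst-case growth is exponential in h, so
the search carries a budget (`max_leaves`, default 10⁶ across scan states,
pairing products, and emitted classes) and raises a clear error beyond it;
the CLI additionally refuses `--mode all` for 2h > 8 without an explicit
budget or `--force`.

Whether a scan leaf could ever reach an infeasible assembly for a valid M
is not settled by the theory as stated; the implementation asserts
non-emptiness of every per-median solution set and would surface a
diagnostic rather than silently skip.

## Oracle and synthetic instances

The brute-force oracle answers the same question as the enumerator with
none of the CWF machinery: enumerate candidate multisets over the
C(n, w̄)-string universe, keep those whose composition grid equals M, and
collect canonical classes.  Two routes exist: full enumeration of a
universe grouped by serialized grid (used to sweep every M of a small
universe at once), and a depth-first search in nondecreasing string order
that prunes any partial multiset whose grid is not componentwise dominated
by the target — a pure feasibility cut (adding strings only adds counts),
so the result is identical to scoring the full enumeration while making
n ≤ 10, h ≤ 3 spot checks cheap.

Synthetic instances place, per string, w̄ ones on a uniformly sampled
position subset via Python's seeded `random.Random.sample` (a documented,
platform-stable stream), so fixtures are reproducible everywhere.  The
generator emulates exactly the study conditions — error-free composition
readout of same-length, same-weight strings.  It does *not* model
composition noise, missing fragments, non-constant weight, or non-binary
alphabets, so passing tests say nothing about those regimes (all are out of
scope here).

## Verification scale and numerical choices

All arithmetic is exact integer arithmetic on numpy int64 grids; there are
no tolerances, and ties cannot arise (the greedy slab location is strict,
enumeration orders are total).  Degenerate inputs are exercised: w̄ = 0 or
w̄ = n (flat CWFs), n = 1, h = 1, palindromic members, duplicate members.

The correctness battery cross-checks the enumerator, the uniqueness test,
and the oracle on every constant-weight composition multiset with n ≤ 7,
h ≤ 2 (730 distinct grids, exhaustive over all weights) and on 200 seeded
random instances with n ≤ 10, h ≤ 3, alongside property tests (seeded /
derandomized hypothesis) for the grid identities, the mirror symmetry of
interval lists, solution preservation under swaps, and the greedy
contract.  These sizes keep the default suite under a few seconds while
the exhaustive part already covers every branch of the scan/assembly
combinatorics reachable at small h; the reference-instance checks (n = 6,
h = 3 and n = 7, h = 4, including the 73,815-candidate brute force) run in
under a second each.

## Known limitations

* The enumerator is exponential in the worst case by nature of the
  problem; the budget turns pathological inputs into clean errors, not
  answers.
* Externally supplied composition tables are validated against every grid
  invariant, but a grid can pass validation yet admit no string multiset;
  such inputs surface as assertion failures in the scan/assembly stages
  rather than as a dedicated infeasibility proof.
* Only binary alphabets and constant-weight instances are supported;
  prefix–suffix data (not all-substring data) is the only readout model.
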