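"""Online Sequitur grammar induction and hierarchy depth.

Sequitur incrementally builds a context-free grammar that generates exactly
one string, by replacing every repeated pair of adjacent symbols (digram)
with a reference to a rule.  Two constraints are enforced as each symbol is
appended:

* digram uniqueness — no digram occurs more than once (non-overlapping)
  across all rule bodies;
* rule utility — every rule other than the start rule is referenced at
  least twice; a rule that drops to a single reference is inlined.

Repairs are scheduled most-recently-created digram first, with rule-utility
inlining applied once the digram queue drains; this work-list formulation
closes the corner case of the classic linked-list implementation in which a
digram suppressed as self-overlapping (``bbb``) can silently duplicate
after its left neighbour is rewritten.

The nesting of rules gives the string a hierarchy; :func:`grammar_depth` is
the length of the longest chain of rule references below the start rule —
the quantitative measure of hierarchical structure used throughout this
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = ["Grammar", "GrammarError", "induce_grammar", "grammar_depth"]


class GrammarError(ValueError):
    """Raised for structurally invalid grammars (e.g. cyclic references)."""


@dataclass(frozen=True)
class Grammar:
    """An induced grammar: a start production plus numbered rules.

    Productions are tuples whose elements are terminals (1-char ``str``) or
    rule ids (``int``).  Rule ids are assigned in creation order during
    induction and renumbered compactly on extraction.
    """

    start: tuple
    rules: dict[int, tuple]

    def expand(self) -> str:
        """Expand the start production back into the generated string."""
        out: list[str] = []
        stack = list(reversed(self.start))
        budget = 10_000_000  # guards against cyclic hand-built grammars
        while stack:
            budget -= 1
            if budget < 0:
                raise GrammarError("expansion did not terminate (cyclic grammar?)")
            sym = stack.pop()
            if isinstance(sym, int):
                stack.extend(reversed(self.rules[sym]))
            else:
                out.append(sym)
        return "".join(out)

    def reference_counts(self) -> dict[int, int]:
        counts = {rid: 0 for rid in self.rules}
        for body in self._all_bodies():
            for sym in body:
                if isinstance(sym, int):
                    counts[sym] += 1
        return counts

    def _all_bodies(self) -> Iterator[tuple]:
        yield self.start
        yield from self.rules.values()

    def check_rule_utility(self) -> bool:
        """Every rule is referenced at least twice and has body length >= 2."""
        counts = self.reference_counts()
        return all(c >= 2 for c in counts.values()) and all(
            len(b) >= 2 for b in self.rules.values()
        )

    def check_digram_uniqueness(self) -> bool:
        """No digram occurs twice, counting overlapping runs (``aaa``) once."""
        seen: dict[tuple, tuple] = {}
        for bid, body in enumerate(self._all_bodies()):
            for i in range(len(body) - 1):
                d = (body[i], body[i + 1])
                prev = seen.get(d)
                if prev is None:
                    seen[d] = (bid, i)
                elif prev == (bid, i - 1):
                    # overlapping occurrence within a run such as "aaa"
                    continue
                else:
                    return False
        return True


# ---------------------------------------------------------------------------
# internal linked-list machinery


class _Rule:
    __slots__ = ("rid", "guard", "refcount")

    def __init__(self, rid: int):
        self.rid = rid
        self.refcount = 0
        g = _Sym(self, guard=True)
        g.prev = g
        g.next = g
        self.guard = g

    @property
    def first(self) -> "_Sym":
        return self.guard.next

    @property
    def last(self) -> "_Sym":
        return self.guard.prev


class _Sym:
    __slots__ = ("value", "prev", "next", "guard", "dead")

    def __init__(self, value, guard: bool = False):
        self.value = value  # terminal str, or _Rule for nonterminals/guards
        self.prev: "_Sym | None" = None
        self.next: "_Sym | None" = None
        self.guard = guard
        self.dead = False

    @property
    def is_nonterminal(self) -> bool:
        return (not self.guard) and isinstance(self.value, _Rule)

    def key(self):
        return ("r", self.value.rid) if isinstance(self.value, _Rule) else ("t", self.value)


def _join(left: _Sym, right: _Sym) -> None:
    left.next = right
    right.prev = left


class _Sequitur:
    """The online induction engine (one instance per input string)."""

    def __init__(self):
        self.index: dict[tuple, _Sym] = {}
        self._next_rid = 1
        self.start = self._new_rule()
        self.rules: dict[int, _Rule] = {}  # live rules other than start
        self.work: list[_Sym] = []  # LIFO queue of left symbols of digrams to check

    def _new_rule(self) -> _Rule:
        r = _Rule(self._next_rid)
        self._next_rid += 1
        return r

    # -- digram index ------------------------------------------------------

    @staticmethod
    def _digram_key(s: _Sym) -> tuple:
        return (s.key(), s.next.key())

    def _lookup(self, key: tuple) -> "_Sym | None":
        # entries can go stale when a stored symbol's neighbourhood is
        # rewritten; validate against current values on every lookup
        m = self.index.get(key)
        if m is None:
            return None
        if m.dead or m.guard or m.next is None or m.next.guard or self._digram_key(m) != key:
            del self.index[key]
            return None
        return m

    def _forget_digram(self, s: _Sym) -> None:
        if s.guard or s.next is None or s.next.guard:
            return
        key = self._digram_key(s)
        if self.index.get(key) is s:
            del self.index[key]

    # -- structural edits --------------------------------------------------

    def _insert_after(self, node: _Sym, new: _Sym) -> None:
        _join(new, node.next)
        _join(node, new)

    def _delete(self, s: _Sym) -> None:
        self._forget_digram(s)
        _join(s.prev, s.next)
        if s.is_nonterminal:
            s.value.refcount -= 1
        s.dead = True

    def _make_ref(self, rule: _Rule) -> _Sym:
        rule.refcount += 1
        return _Sym(rule)

    def _copy_sym(self, s: _Sym) -> _Sym:
        if s.is_nonterminal:
            return self._make_ref(s.value)
        return _Sym(s.value)

    def _enqueue(self, *syms: _Sym) -> None:
        self.work.extend(syms)

    # -- constraint enforcement -------------------------------------------

    def push(self, ch: str) -> None:
        """Append one terminal to the start rule and restore the invariants."""
        last = self.start.last
        self._insert_after(last, _Sym(ch))
        self._enqueue(last)
        self._settle()

    def _settle(self) -> None:
        guard = 0
        while self.work or self._fix_one_underused_rule():
            while self.work:
                guard += 1
                if guard > 1_000_000:
                    raise GrammarError("repair cascade did not terminate")
                s = self.work.pop()
                if s.dead or s.guard or s.next is None or s.next.guard:
                    continue
                self._check(s)

    def _check(self, s: _Sym) -> None:
        """Check the digram starting at ``s``; repair if it repeats."""
        key = self._digram_key(s)
        m = self._lookup(key)
        if m is None:
            self.index[key] = s
        elif m is not s and m.next is not s and s.next is not m:
            # a genuine (non-overlapping, distinct) repeat
            self._match(s, m)

    def _match(self, ss: _Sym, m: _Sym) -> None:
        if m.prev.guard and m.next.next.guard:
            # the matched occurrence is a complete rule body: reuse that rule
            self._substitute(ss, m.prev.value)
        elif ss.prev.guard and ss.next.next.guard:
            self._substitute(m, ss.prev.value)
        else:
            r = self._new_rule()
            self._insert_after(r.last, self._copy_sym(ss))
            self._insert_after(r.last, self._copy_sym(ss.next))
            self.rules[r.rid] = r
            self._substitute(m, r)
            self._substitute(ss, r)
            self.index[self._digram_key(r.first)] = r.first

    def _substitute(self, s: _Sym, r: _Rule) -> None:
        """Replace the digram starting at ``s`` with a reference to ``r``."""
        q = s.prev
        self._delete(s)
        self._delete(q.next)
        ref = self._make_ref(r)
        self._insert_after(q, ref)
        # recheck the rewritten neighbourhood, most recent digram (q, ref)
        # last so it pops first
        self._enqueue(ref.next, q.prev, ref, q)

    def _fix_one_underused_rule(self) -> bool:
        """Repair one rule violating utility (refcount < 2 or body < 2)."""
        for rid in sorted(self.rules, reverse=True):
            rule = self.rules[rid]
            if rule.refcount == 0:
                self._retire_rule(rule)
                return True
            if rule.refcount == 1:
                self._expand(self._find_reference(rule))
                return True
            if self._body_len(rule) < 2:
                self._dissolve_unit_rule(rule)
                return True
        return False

    @staticmethod
    def _body_len(rule: _Rule) -> int:
        n, s = 0, rule.first
        while not s.guard:
            n += 1
            s = s.next
        return n

    def _retire_rule(self, rule: _Rule) -> None:
        """Drop a rule that nothing references any more."""
        s = rule.first
        while not s.guard:
            self._forget_digram(s)
            s.dead = True
            if s.is_nonterminal:
                s.value.refcount -= 1
            s = s.next
        del self.rules[rule.rid]

    def _dissolve_unit_rule(self, rule: _Rule) -> None:
        """Replace every reference to a single-symbol rule by its body symbol."""
        inner = rule.first
        refs = []
        for host in [self.start, *self.rules.values()]:
            s = host.first
            while not s.guard:
                if s.is_nonterminal and s.value is rule:
                    refs.append(s)
                s = s.next
        for ref in refs:
            q = ref.prev
            self._delete(ref)
            self._insert_after(q, self._copy_sym(inner))
            self._enqueue(q.next, q)
        self._retire_rule(rule)

    def _find_reference(self, rule: _Rule) -> _Sym:
        for host in [self.start, *self.rules.values()]:
            s = host.first
            while not s.guard:
                if s.is_nonterminal and s.value is rule:
                    return s
                s = s.next
        raise GrammarError(f"unreferenced rule {rule.rid}")  # pragma: no cover

    def _expand(self, ref: _Sym) -> None:
        """Inline the (single) use of ``ref``'s rule and retire the rule."""
        rule: _Rule = ref.value
        left, right = ref.prev, ref.next
        first, last = rule.first, rule.last
        self._forget_digram(left)
        self._forget_digram(ref)
        ref.dead = True
        _join(left, first)
        _join(last, right)
        del self.rules[rule.rid]
        self._enqueue(right, last, left.prev, left)

    # -- extraction --------------------------------------------------------

    def to_grammar(self) -> Grammar:
        def body(rule: _Rule) -> tuple:
            out = []
            s = rule.first
            while not s.guard:
                out.append(s.value.rid if isinstance(s.value, _Rule) else s.value)
                s = s.next
            return tuple(out)

        start = body(self.start)
        bodies: dict[int, tuple] = {}
        todo = [sym for sym in start if isinstance(sym, int)]
        while todo:
            rid = todo.pop()
            if rid in bodies:
                continue
            b = body(self.rules[rid])
            bodies[rid] = b
            todo.extend(sym for sym in b if isinstance(sym, int))
        # renumber in creation order for stable, compact ids
        order = {rid: i + 1 for i, rid in enumerate(sorted(bodies))}
        remap = lambda sym: order[sym] if isinstance(sym, int) else sym
        return Grammar(
            start=tuple(remap(s) for s in start),
            rules={order[rid]: tuple(remap(s) for s in b) for rid, b in bodies.items()},
        )


# ---------------------------------------------------------------------------
# public API


def induce_grammar(s: str) -> Grammar:
    """Run Sequitur on ``s`` and return the induced grammar.

    The result is lossless (``grammar.expand() == s``) and satisfies digram
    uniqueness and rule utility.
    """
    eng = _Sequitur()
    for ch in s:
        eng.push(ch)
    return eng.to_grammar()


def grammar_depth(g: Grammar) -> int:
    """Longest chain of nested rule references below the start production.

    A rule-free grammar has depth 0; a start production referencing rule A
    whose body is all terminals has depth 1.  Raises :class:`GrammarError`
    on cyclic reference graphs.
    """
    in_progress = object()
    memo: dict[int, object] = {}

    def rule_depth(rid: int) -> int:
        got = memo.get(rid)
        if got is in_progress:
            raise GrammarError(f"cyclic rule reference through rule {rid}")
        if got is not None:
            return got  # type: ignore[return-value]
        memo[rid] = in_progress
        body = g.rules.get(rid)
        if body is None:
            raise GrammarError(f"dangling reference to rule {rid}")
        d = 1 + max((rule_depth(s) for s in body if isinstance(s, int)), default=0)
        memo[rid] = d
        return d

    return max((rule_depth(s) for s in g.start if isinstance(s, int)), default=0)
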