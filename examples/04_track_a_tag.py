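"""Follow one emerging tag through time: role trajectory, dominant role
before and after its breakout, and the neighbors most relevant to a hub.

The generator plants "emerging" tags that are rare for the first year and
common afterwards. Their role mixture should migrate from the peripheral
role toward the central one across the changepoint.
"""


from taggraph import (
    GeneratorConfig,
    build_taggraph,
    compute_features,
    factorize,
    generate_corpus,
    neighbor_frequency,
    role_trajectory,
    top_k_neighbors,
)

corpus, truth = generate_corpus(GeneratorConfig(seed=0))
series = build_taggraph(corpus)
tensor = compute_features(series)
model = factorize(tensor, r=5, seed=0)

tag = truth.emerging_tags[0]
traj = role_trajectory(model, tag)
quarter = len(series) // 4
first = traj.iloc[:quarter].mean(skipna=True)
last = traj.iloc[-quarter:].mean(skipna=True)
print(f"emerging tag {tag!r} (breakout at {truth.changepoint_month}):")
print(f"  dominant role, first quarter: {first.idxmax()} (mixture {first.max():.2f})")
print(f"  dominant role, last quarter:  {last.idxmax()} (mixture {last.max():.2f})")
# a change of dominant role across the breakout is the transition signal

hub = truth.hub_tags[0]
t_late = len(series) - 1
ranking = top_k_neighbors(series, model, hub, role=0, t=t_late, k=5)
print(f"\ntop-5 neighbors of hub {hub!r} for role 0 in {ranking.month}:")
for rank, (neighbor, relevance) in enumerate(ranking.ranked, 1):
    print(f"  {rank}. {neighbor}  relevance={relevance:.4f}")
# relevance = edge association strength x the neighbor's role-0 relevance

counts = neighbor_frequency(series, model, hub, role=0, k=20)
top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
print(f"\nmost persistent role-0 neighbors of {hub!r} across {len(series)} months:")
for neighbor, months in top:
    print(f"  {neighbor}: in the top-20 ranking for {months} months")
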