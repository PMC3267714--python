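# Macro-level inputs for national extrapolation.
# exchange_rate_inr_per_usd is 1713/38, the rate implied by the per-capita
# pair "INR 1713 (USD 38)"; no explicit rate is published.
national_population: 1200000000
gdp_per_capita_usd: 1176
exchange_rate_inr_per_usd: 45.078947368421055
preventive_cost_per_capita_inr: 300
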