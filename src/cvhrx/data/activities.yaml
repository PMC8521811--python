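# Youth activity menu with MET values (compendium-style energy costs).
# intensity is derived from MET at load time: light <3.0, moderate 3.0-<6.0,
# vigorous >=6.0. tags drive region/context filtering and family options.
- {name: walking the dog,          met: 3.0,  tags: [outdoor, family_oriented]}
- {name: brisk family walk,        met: 3.5,  tags: [outdoor, family_oriented]}
- {name: swimming (leisure),       met: 6.0,  tags: [water, indoor]}
- {name: playing basketball,       met: 6.5,  tags: [team, outdoor, indoor]}
- {name: dancing,                  met: 5.0,  tags: [indoor, family_oriented]}
- {name: bicycling (leisure),      met: 4.0,  tags: [outdoor]}
- {name: soccer (casual),          met: 7.0,  tags: [team, outdoor]}
- {name: hiking,                   met: 5.3,  tags: [outdoor, family_oriented]}
- {name: jumping rope,             met: 8.8,  tags: [indoor, outdoor]}
- {name: skateboarding,            met: 5.0,  tags: [outdoor]}
- {name: active video games,       met: 3.8,  tags: [indoor]}
- {name: stretching / gentle yoga, met: 2.5,  tags: [indoor, family_oriented]}
- {name: playing catch,            met: 2.5,  tags: [outdoor, family_oriented]}
- {name: surfing,                  met: 3.5,  tags: [outdoor, water, coastal]}
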