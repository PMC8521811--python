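# Stoplight-diet food lists per target eating behavior: green "anytime",
# yellow "sometimes", red "rarely". Content is editable data, not code.
fruit:
  goal: "You could aim for 2 or more servings of fruit each day."
  green: [fresh apples, bananas, berries, oranges, melon]
  yellow: [canned fruit in 100% juice, dried fruit, small glass of 100% fruit juice]
  red: [fruit snacks and gummies, fruit canned in syrup, fruit-filled pastries]
vegetable:
  goal: "You may try adding vegetables to 2 or more meals each day."
  green: [carrot sticks, broccoli, leafy salad greens, cucumber, bell peppers]
  yellow: [corn, baked potato, vegetables with light sauce]
  red: [french fries, fried vegetables, creamed vegetables]
whole_grains:
  goal: "When you have grains, you could choose whole-grain versions."
  green: [oatmeal, whole-grain bread, brown rice, whole-grain cereal]
  yellow: [white rice, plain pasta, flour tortillas]
  red: [sugary cereal, doughnuts, snack cakes]
ssb:
  goal: "You may swap sugary drinks for water or milk most days."
  green: [water, plain sparkling water, fat-free or low-fat milk]
  yellow: [flavored milk, small glass of 100% fruit juice]
  red: [soda, sweet tea, sports drinks, energy drinks]
snacking:
  goal: "For snacks, you could reach for fruit or veggies first."
  green: [vegetable sticks, fresh fruit, plain low-fat yogurt, air-popped popcorn]
  yellow: [pretzels, granola bars, buttered popcorn]
  red: [chips, candy, cookies, ice cream]
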