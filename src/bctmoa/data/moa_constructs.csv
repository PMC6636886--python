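id,label,definition,source
1,Knowledge,an awareness of the existence of something,TDF-domain
2,Skills,an ability or proficiency acquired through practice,TDF-domain
3,Social/Professional Role and Identity,a coherent set of behaviors and displayed personal qualities of an individual in a social or work setting,TDF-domain
4,Beliefs about Capabilities,beliefs about one's ability to successfully carry out a behavior,TDF-domain
5,Optimism,confidence that things will happen for the best or that desired goals will be attained,TDF-domain
6,Beliefs about Consequences,"beliefs about the consequences of a behavior (i.e., perceptions about what will be achieved and/or lost by undertaking a behavior, as well as the probability that a behavior will lead to a specific outcome)",TDF-domain
7,Reinforcement,processes by which the frequency or probability of a response is increased through a dependent relationship or contingency with a stimulus or circumstance,TDF-domain
8,Intention,a conscious decision to perform a behavior or a resolve to act in a certain way,TDF-domain
9,Goals,mental representations of outcomes or end states that an individual wants to achieve,TDF-domain
10,"Memory, Attention and Decision Processes","ability to retain information, focus on aspects of the environment, and choose between two or more alternatives",TDF-domain
11,Environmental Context and Resources,aspects of a person's situation or environment that discourage or encourage the behavior,TDF-domain
12,Social Influences,"those interpersonal processes that can cause oneself to change one's thoughts, feelings or behaviors",TDF-domain
13,Emotion,"a complex reaction pattern involving experiential, behavioral, and physiological elements",TDF-domain
14,Behavioral Regulation,"behavioral, cognitive, and/or emotional skills for managing or changing behavior",TDF-domain
15,Norms,the attitudes held and behaviors exhibited by other people within a social group,theory-derived
16,Subjective Norms,one's perceptions of what most other people within a social group believe and do,theory-derived
17,Attitude Towards the Behavior,the general evaluations of the behavior on a scale ranging from negative to positive,theory-derived
18,Motivation,processes relating to the impetus that gives purpose or direction to behavior and operates at a conscious or unconscious level,theory-derived
19,Self-Image,"one's conception and evaluation of oneself, including psychological and physical characteristics, qualities, and skills",theory-derived
20,Needs,"deficit of something required for survival, well-being, or personal fulfillment",theory-derived
21,Values,"moral, social, or aesthetic principles accepted by an individual or society as a guide to what is good, desirable, or important",theory-derived
22,Feedback Processes,processes through which current behavior is compared against a particular standard,theory-derived
23,Social Learning/Imitation,"a process by which thoughts, feelings, and motivational states observed in others are internalized and replicated without the need for conscious awareness",theory-derived
24,Behavioral Cueing,"processes by which behavior is triggered from either the external environment, the performance of another behavior, or from ideas appearing in consciousness",theory-derived
25,General Attitudes/Beliefs,"evaluations of an object, person, group, issue, or concept on a scale ranging from negative to positive",theory-derived
26,Perceived Susceptibility/Vulnerability,perceptions of the likelihood that one is vulnerable to a threat,theory-derived
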