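qid,set_id,category,element1,element2,goal,language
1,1,SIG,Digital camera,Coloring book,Foster personal creativity and expression,en
2,1,SIG,Virtual reality (VR) headset,Pet fish,Reduce feelings of loneliness and isolation,en
3,1,SIG,Desk lamp,Water filter,Encourage regular hydration (water consumption),en
4,1,SIG,Refrigerator,Allergy alert App,Assist in managing dietary restrictions,en
5,1,SIG,Padlock,Web browser,Protect personal digital privacy,en
6,2,SIG,Shopping cart,Barcode scanner,Simplify grocery shopping,en
7,2,SIG,Voice recorder,Language learning App,Enhance personal communication skills,en
8,2,SIG,Stress ball,Meditation App,Strengthen one's capacity to endure and manage difficult times,en
9,2,SIG,YouTube,Puzzle,Assist in pursuing a new skill,en
10,2,SIG,Elevator,E-Library,Enable easier access to books or learning materials,en
11,3,SIG,Piggy bank,Spreadsheet software,Simplify personal budgeting and saving,en
12,3,SIG,Baby monitor,Parenting blog,Provide tools for effective parenting,en
13,3,SIG,Digital wallet,Review platform,Ensure a safe online shopping experience,en
14,3,SIG,Blender,Health and nutrition database,Strengthen immune system health,en
15,3,SIG,GPS device,Wardrobe closet,Improve your fashion choices and grooming routine,en
16,4,SIG,Webcam,Motion detector lights,Enhance home security,en
17,4,SIG,Hammock,Meditation App,Promote mental relaxation,en
18,4,SIG,Music streaming app (like Spotify),Potted plant,Improve mental well-being,en
19,4,SIG,Filing cabinet,Smartphone reminder App,Improve personal space organization,en
20,4,SIG,Interactive quiz App,Microwave oven,Enhance learning opportunities outside of formal education,en
21,5,SIG,Vacuum cleaner,Calendar App,Make household tasks more efficient,en
22,5,SIG,Walking stick,Video calling device,Aid in the care of elderly family members,en
23,5,SIG,Smartphone,Medical journal,Enable access to quality healthcare information,en
24,5,SIG,Smartwatch,Pepper spray,Enhance personal safety,en
25,5,SIG,Public park bench,Social networking site,Encourage positive community engagement,en
26,1,SDG,Electric cars,Travel review websites,Promote eco-friendly travel,en
27,1,SDG,Mobile alert App,Community radio station,Improve disaster preparedness,en
28,1,SDG,Parking lots,Ceramic filters,Create a rainwater collection system for effective water storage,en
29,1,SDG,Shipping containers,Green roof systems,Design affordable housing with minimal environmental impact,en
30,1,SDG,Cryptocurrencies,Job portals,Encourage equal pay for equal work,en
31,2,SDG,Animated series (animation production),Weather station data,Foster education on climate change,en
32,2,SDG,Virtual reality (VR) conferences,University research labs,Promote collaborations to share sustainable technology,en
33,2,SDG,Coffee maker,Bamboo charcoal,Develop more effective ways to purify water for human consumption,en
34,2,SDG,Beeswax,Popsicle sticks,Propose innovative ideas for packaging that is eco-friendly,en
35,2,SDG,3D printers,Local artisanal crafts,To encourage eco-friendly product manufacturing in local community,en
36,3,SDG,Digital billboards,Drones,Enhance public awareness on land conservation,en
37,3,SDG,Virtual reality (VR) games,School curriculum,Encourage youth involvement in projects related to SDGs (Sustainable Development Goals),en
38,3,SDG,Weather Apps,Doorbells with cameras,Design tools for early warning systems for natural disasters,en
39,3,SDG,Maglev train technology,Carpool App,Develop efficient public transportation systems,en
40,3,SDG,Algae,Underground metro systems,Design methods for carbon capture and storage,en
41,4,SDG,Wildlife documentary,Augmented Reality (AR) glass,Encourage biodiversity conservation,en
42,4,SDG,Library system,Refurbished laptops,Promote access to technology in impoverished communities,en
43,4,SDG,Exercise gym equipment,Solar panels,Design systems for clean energy generation,en
44,4,SDG,Vending machines,Recycling Apps,Design sustainable solutions for electronic waste,en
45,4,SDG,Fitness tracker,Local farmer's market,promote health-related projects in impoverished communities,en
46,5,SDG,Rooftops,Hydroponic systems (Water-based gardening systems),Enhance local food production,en
47,5,SDG,Air purifiers,Public buses,Enhance public health through clean air initiatives,en
48,5,SDG,International film festivals,Green technologies (environment-friendly),Encourage international partnerships for SDGs (Sustainable Development Goals),en
49,5,SDG,Bamboo fiber,QR code,Encourage sustainable fashion (Advocate for clothing that's better for the environment),en
50,5,SDG,E-readers,Solar-powered lanterns,Enhance digital literacy in impoverished communities,en
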